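# Synthetic stand-in first-name list (role: proper-name gazetteer).
# Real name lists are a drop-in replacement via lexicon paths.
aaron
abby
adam
alan
alice
amanda
amy
andrea
angela
anita
ann
anna
annie
anthony
barb
barbara
becky
ben
beth
betty
bill
bob
bonnie
brenda
brian
carl
carla
carol
carolyn
cathy
charles
charlotte
cheryl
chris
christine
cindy
claire
clara
connie
craig
cristin
cynthia
dan
dana
daniel
darlene
dave
david
dawn
debbie
deborah
denise
diana
diane
donna
doris
dorothy
doug
ed
edith
edna
elaine
ellen
emily
emma
eric
erin
esther
eva
evelyn
fay
fiona
fran
frances
frank
fred
gail
gary
george
gina
ginger
gladys
glen
gloria
grace
greg
gwen
hannah
harold
harriet
hazel
heather
heidi
helen
henry
holly
howard
irene
iris
jack
jackie
jan
jane
janet
janice
janie
jason
jean
jeanne
jeff
jenna
jennifer
jenny
jerry
jess
jessica
jill
jim
joan
joanne
jodi
joe
joel
john
joyce
juanita
judith
judy
julia
julie
karen
kate
katherine
kathleen
kathryn
kathy
katie
kay
keith
kelly
ken
kevin
kim
kimberly
kris
kristen
kurt
larry
lars
laura
lauren
laurie
leah
lena
leo
leona
leslie
lillian
linda
lisa
liz
lois
loretta
lori
lorraine
louise
lucy
luann
lydia
lynn
mabel
marcia
margaret
maria
marie
marilyn
marsha
martha
mary
maureen
megan
melissa
michael
michelle
mike
mildred
millie
molly
mona
nadine
nancy
naomi
nell
nick
nicki
nina
nora
norma
olga
olive
pam
pamela
pat
patricia
patty
paul
paula
pearl
peggy
penny
phil
phyllis
rachel
ralph
randy
ray
rebecca
regina
renee
rhonda
rita
rob
roberta
robin
roger
ron
rosa
rose
rosemary
ruth
sally
sam
sandra
sandy
sara
sarah
scott
shannon
sharon
sheila
shelley
sherry
shirley
sonia
stacy
stan
stella
steve
sue
susan
suzanne
sylvia
tammy
tanya
ted
teresa
terri
thelma
tina
todd
tom
tony
tracy
valerie
vera
vicki
vickie
viola
violet
virginia
vivian
walt
wanda
wendy
willa
yvonne
zelda
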