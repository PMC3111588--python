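# Synthetic stand-in medical-term list.
arthritis
biopsy
brca1
brca2
cancer
carcinoma
chemo
chemotherapy
diagnosis
dcis
flare
infection
inflammation
joint
lump
lumpectomy
lymph
mammogram
mastectomy
metastasis
mri
mris
nausea
oncologist
oncology
pathology
radiation
recurrence
remission
rheumatoid
scan
surgeon
surgery
swelling
symptom
symptoms
therapy
tumor
ultrasound
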