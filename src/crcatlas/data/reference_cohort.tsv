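disease_group	n_patients	n_ctc_positive
Lung cancer	373	350
Colorectal cancer	310	295
Cervical and uterus cancer	223	203
Gastric cancer	179	166
Nasopharynx cancer	131	101
Liver cancer	116	103
Breast cancer	104	95
Laryngeal cancer	89	74
Pancreatic cancer	76	68
Esophagus cancer	71	69
Ovarian cancer	54	49
Glioma	33	31
Cholangiocarcinoma	31	26
Prostatic cancer	29	27
Bladder cancer	25	25
Lymphoma	20	19
Maxillofacial tumors	19	15
Salivary gland tumors	14	13
Sarcoma (all)	14	9
Thymus and mediastinum tumors	13	13
Renal cancer	12	10
Ampulla cancer	12	12
Skin cancer	8	7
Duodenum tumors	6	6
Reproductive cell tumors	6	6
Cancers of multiple primary	92	87
Cancers of unknown primary	11	11
Undetermined pulmonary nodules	106	94
Precancerous lesions	20	18
Benign lesions	111	104
Infectious diseases	52	51
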