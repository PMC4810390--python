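category,weight,icd_code
Myocardial infarction,1,410
Myocardial infarction,1,412
Congestive heart failure,1,428
Peripheral vascular disease,1,440
Peripheral vascular disease,1,441
Peripheral vascular disease,1,443.9
Peripheral vascular disease,1,447.1
Peripheral vascular disease,1,785.4
Cerebrovascular disease,1,430
Cerebrovascular disease,1,431
Cerebrovascular disease,1,432
Cerebrovascular disease,1,433
Cerebrovascular disease,1,434
Cerebrovascular disease,1,435
Cerebrovascular disease,1,436
Cerebrovascular disease,1,437
Cerebrovascular disease,1,438
Dementia,1,290
Chronic pulmonary disease,1,490
Chronic pulmonary disease,1,491
Chronic pulmonary disease,1,492
Chronic pulmonary disease,1,493
Chronic pulmonary disease,1,494
Chronic pulmonary disease,1,495
Chronic pulmonary disease,1,496
Chronic pulmonary disease,1,500
Chronic pulmonary disease,1,501
Chronic pulmonary disease,1,502
Chronic pulmonary disease,1,503
Chronic pulmonary disease,1,504
Chronic pulmonary disease,1,505
Chronic pulmonary disease,1,506.4
Rheumatologic disease,1,710.0
Rheumatologic disease,1,710.1
Rheumatologic disease,1,710.4
Rheumatologic disease,1,714.0
Rheumatologic disease,1,714.1
Rheumatologic disease,1,714.2
Rheumatologic disease,1,714.81
Rheumatologic disease,1,725
Peptic ulcer disease,1,531
Peptic ulcer disease,1,532
Peptic ulcer disease,1,533
Peptic ulcer disease,1,534
Mild liver disease,1,571.2
Mild liver disease,1,571.4
Mild liver disease,1,571.5
Mild liver disease,1,571.6
Diabetes (mild to moderate),1,250.0
Diabetes (mild to moderate),1,250.1
Diabetes (mild to moderate),1,250.2
Diabetes (mild to moderate),1,250.3
Diabetes (mild to moderate),1,250.7
Diabetes with chronic complications,2,250.4
Diabetes with chronic complications,2,250.5
Diabetes with chronic complications,2,250.6
Hemiplegia or paraplegia,2,342
Hemiplegia or paraplegia,2,344.1
Renal disease,2,582
Renal disease,2,583
Renal disease,2,585
Renal disease,2,586
Renal disease,2,588
"Any malignancy, including lymphoma and leukemia",2,140
"Any malignancy, including lymphoma and leukemia",2,141
"Any malignancy, including lymphoma and leukemia",2,142
"Any malignancy, including lymphoma and leukemia",2,143
"Any malignancy, including lymphoma and leukemia",2,144
"Any malignancy, including lymphoma and leukemia",2,145
"Any malignancy, including lymphoma and leukemia",2,146
"Any malignancy, including lymphoma and leukemia",2,147
"Any malignancy, including lymphoma and leukemia",2,148
"Any malignancy, including lymphoma and leukemia",2,149
"Any malignancy, including lymphoma and leukemia",2,150
"Any malignancy, including lymphoma and leukemia",2,151
"Any malignancy, including lymphoma and leukemia",2,152
"Any malignancy, including lymphoma and leukemia",2,153
"Any malignancy, including lymphoma and leukemia",2,154
"Any malignancy, including lymphoma and leukemia",2,155
"Any malignancy, including lymphoma and leukemia",2,156
"Any malignancy, including lymphoma and leukemia",2,157
"Any malignancy, including lymphoma and leukemia",2,158
"Any malignancy, including lymphoma and leukemia",2,159
"Any malignancy, including lymphoma and leukemia",2,160
"Any malignancy, including lymphoma and leukemia",2,161
"Any malignancy, including lymphoma and leukemia",2,162
"Any malignancy, including lymphoma and leukemia",2,163
"Any malignancy, including lymphoma and leukemia",2,164
"Any malignancy, including lymphoma and leukemia",2,165
"Any malignancy, including lymphoma and leukemia",2,166
"Any malignancy, including lymphoma and leukemia",2,167
"Any malignancy, including lymphoma and leukemia",2,168
"Any malignancy, including lymphoma and leukemia",2,169
"Any malignancy, including lymphoma and leukemia",2,170
"Any malignancy, including lymphoma and leukemia",2,171
"Any malignancy, including lymphoma and leukemia",2,172
"Any malignancy, including lymphoma and leukemia",2,174
"Any malignancy, including lymphoma and leukemia",2,175
"Any malignancy, including lymphoma and leukemia",2,176
"Any malignancy, including lymphoma and leukemia",2,177
"Any malignancy, including lymphoma and leukemia",2,178
"Any malignancy, including lymphoma and leukemia",2,179
"Any malignancy, including lymphoma and leukemia",2,180
"Any malignancy, including lymphoma and leukemia",2,181
"Any malignancy, including lymphoma and leukemia",2,182
"Any malignancy, including lymphoma and leukemia",2,183
"Any malignancy, including lymphoma and leukemia",2,184
"Any malignancy, including lymphoma and leukemia",2,185
"Any malignancy, including lymphoma and leukemia",2,186
"Any malignancy, including lymphoma and leukemia",2,187
"Any malignancy, including lymphoma and leukemia",2,188
"Any malignancy, including lymphoma and leukemia",2,189
"Any malignancy, including lymphoma and leukemia",2,190
"Any malignancy, including lymphoma and leukemia",2,191
"Any malignancy, including lymphoma and leukemia",2,192
"Any malignancy, including lymphoma and leukemia",2,193
"Any malignancy, including lymphoma and leukemia",2,194
"Any malignancy, including lymphoma and leukemia",2,195
"Any malignancy, including lymphoma and leukemia",2,200
"Any malignancy, including lymphoma and leukemia",2,201
"Any malignancy, including lymphoma and leukemia",2,202
"Any malignancy, including lymphoma and leukemia",2,203
"Any malignancy, including lymphoma and leukemia",2,204
"Any malignancy, including lymphoma and leukemia",2,205
"Any malignancy, including lymphoma and leukemia",2,206
"Any malignancy, including lymphoma and leukemia",2,207
"Any malignancy, including lymphoma and leukemia",2,208
Moderate or severe liver disease,3,456.0
Moderate or severe liver disease,3,456.1
Moderate or severe liver disease,3,456.2
Moderate or severe liver disease,3,572.2
Moderate or severe liver disease,3,572.3
Moderate or severe liver disease,3,572.4
Moderate or severe liver disease,3,572.8
Metastatic solid tumor,6,196
Metastatic solid tumor,6,197
Metastatic solid tumor,6,198
Metastatic solid tumor,6,199
AIDS,6,042
AIDS,6,043
AIDS,6,044
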