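# Primary-site vocabulary -> tumour growth class (slow / moderate / rapid).
# Editable: pass a copy of this file to load_site_vocabulary() to override.
breast	slow
prostate	slow
thyroid	slow
multiple_myeloma	slow
lymphoma	slow
renal_cell	moderate
endometrial	moderate
ovarian	moderate
sarcoma	moderate
other	moderate
lung	rapid
colorectal	rapid
gastric	rapid
pancreatic	rapid
head_and_neck	rapid
esophageal	rapid
other_urological	rapid
melanoma	rapid
hepatocellular	rapid
gall_bladder	rapid
cervical	rapid
unknown_origin	rapid
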