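# Example cohort schema: the Budd-Chiari recurrence study variable set.
# The first category of each categorical column is its reference level.
- name: age_group
  kind: categorical
  categories: ["<=50", ">50"]
- name: occupation
  kind: categorical
  categories: [others, farmer_or_worker]
- name: bcs_type
  kind: categorical
  categories: [inferior_vena_cava, hepatic_vein, mixed]
- name: intervention
  kind: categorical
  categories: [balloon_dilation, stent_implantation, catheter_thrombolysis, tips]
- name: NEU
  kind: continuous
- name: PLT
  kind: continuous
- name: PT
  kind: continuous
- name: ALB
  kind: continuous
- name: GLU
  kind: continuous
- name: AFP
  kind: continuous
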