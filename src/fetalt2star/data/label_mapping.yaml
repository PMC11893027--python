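# Default merge of a 19-label fetal-brain parcellation into the seven
# analysis categories. The raw label inventory follows the common fetal
# segmentation convention (left/right pairs and substructures); edit this
# file to match the id scheme of your own parcellation. Package convention:
# corpus-callosum-like white-matter substructures belong to white_matter,
# the vermis to the cerebellum category, and all ventricular spaces
# (lateral, third, fourth, cavum) to ventricles.
mapping:
  1: eCSF                 # external CSF, left
  2: eCSF                 # external CSF, right
  3: gray_matter          # cortical gray matter, left
  4: gray_matter          # cortical gray matter, right
  5: white_matter         # fetal white matter, left
  6: white_matter         # fetal white matter, right
  7: ventricles           # lateral ventricle, left
  8: ventricles           # lateral ventricle, right
  9: ventricles           # cavum septum pellucidum
  10: brainstem
  11: cerebellum          # cerebellar hemisphere, left
  12: cerebellum          # cerebellar hemisphere, right
  13: cerebellum          # cerebellar vermis
  14: deep_gray_matter    # basal ganglia, left
  15: deep_gray_matter    # basal ganglia, right
  16: deep_gray_matter    # thalamus, left
  17: deep_gray_matter    # thalamus, right
  18: ventricles          # third ventricle
  19: ventricles          # fourth ventricle
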