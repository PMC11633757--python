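# Tissue-class taxonomy codebook, version 1.
# Integer codes are the values stored in label rasters (PNG/TIFF).
version: 1
levels:
  15:
    names:
      0: background
      1: epithelium
      2: squamous epithelium
      3: necrosis
      4: tumor
      5: tumor stroma
      6: dysplasia
      7: stroma with inflammation
      8: muscle
      9: connective tissue
      10: adipose tissue
      11: blood vessels
      12: cartilage
      13: glandular tissue
      14: other
  6:
    names:
      0: background
      1: healthy epithelium
      2: tumor stroma
      3: other tissue
      4: necrosis
      5: tumor
  3:
    names:
      0: background
      1: tissue to resect
      2: tissue to preserve
# child label -> parent label, by name
regroup:
  15to6:
    background: background
    epithelium: healthy epithelium
    squamous epithelium: healthy epithelium
    necrosis: necrosis
    tumor: tumor
    tumor stroma: tumor stroma
    dysplasia: tumor
    stroma with inflammation: other tissue
    muscle: other tissue
    connective tissue: other tissue
    adipose tissue: other tissue
    blood vessels: other tissue
    cartilage: other tissue
    glandular tissue: other tissue
    other: other tissue
  6to3:
    background: background
    tumor: tissue to resect
    necrosis: tissue to resect
    tumor stroma: tissue to resect
    healthy epithelium: tissue to preserve
    other tissue: tissue to preserve
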