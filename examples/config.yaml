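# Example generation config: a small two-crypt healthy sample imaging all
# six proteins, with a population-representative mutation draw.
seed: 7
scaffold:
  width: 512
  height: 512
  magnification: "20x"   # sets pixel_size_um: 0.5 (40x -> 0.25)
  grade: healthy
  crypt_count: 2
proteins:
  MLH1: {imaged: true, epithelial_fraction: 0.9}
  PMS2: {imaged: true}
  MSH2: {imaged: true}
  MSH6: {imaged: true}
  P53: {imaged: true}
  PTEN: {imaged: true}
mutation:
  representative: true
  gene: null             # set to MLH1/PMS2/MSH2/MSH6 to pin the mutation
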