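# Four analysis regions: deep/superficial halves of two cortical areas,
# in raw-grid node indices ([ix0, ix1) columns = depth, [iy0, iy1) rows).
regions:
  - {name: area1_superficial, ix0: 0, ix1: 5, iy0: 0, iy1: 5}
  - {name: area1_deep,        ix0: 5, ix1: 10, iy0: 0, iy1: 5}
  - {name: area2_superficial, ix0: 0, ix1: 5, iy0: 5, iy1: 10}
  - {name: area2_deep,        ix0: 5, ix1: 10, iy0: 5, iy1: 10}
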