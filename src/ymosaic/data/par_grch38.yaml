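# GRCh38 pseudoautosomal regions, 1-based inclusive coordinates.
par_regions:
  - {name: PAR1, chrom: X, start: 10001, end: 2781479}
  - {name: PAR1, chrom: Y, start: 10001, end: 2781479}
  - {name: PAR2, chrom: X, start: 155701383, end: 156030895}
  - {name: PAR2, chrom: Y, start: 56887903, end: 57217415}
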