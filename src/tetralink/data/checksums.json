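{
  "core_lipids.tsv": "9df1a50fce13b2ec78408f611e771312b5230f71c981db7758eedcced80b1ac4",
  "polar_lipids.tsv": "729865620252f381d404a42b8999c0bc1fde053d03de026657b1ff88ea42d079",
  "spring_geochemistry.tsv": "76abd49818573698599d17ffff4d78870c43445dafe972e78139558dd891b177"
}
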