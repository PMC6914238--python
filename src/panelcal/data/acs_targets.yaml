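# National marginal raking targets for the three core demographic
# variables: 2017 adult (18+) population distribution from the American
# Community Survey.  Proportions are on the 0-1 scale.
N: 252063800
source: ACS 2017
variables:
  age:
    - {level: "18-24", proportion: 0.1223}
    - {level: "25-34", proportion: 0.1780}
    - {level: "35-44", proportion: 0.1639}
    - {level: "45-54", proportion: 0.1677}
    - {level: "55-64", proportion: 0.1666}
    - {level: "65+",   proportion: 0.2015}
  sex:
    - {level: "male",   proportion: 0.4867}
    - {level: "female", proportion: 0.5133}
  region:
    - {level: "Northeast", proportion: 0.1774}
    - {level: "Midwest",   proportion: 0.2090}
    - {level: "South",     proportion: 0.3774}
    - {level: "West",      proportion: 0.2362}
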