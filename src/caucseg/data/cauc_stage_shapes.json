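{
  "_comment": "Contractual per-stage output shapes [H, W, C] of the full model at 224x224 input. 'D3c' is the first decoder concatenation (the architecture table reuses the label D3 for it); F1-F3 carry the channel-preserving fusion-branch widths 128/64/32.",
  "E1": [224, 224, 64],
  "E2": [224, 224, 16],
  "E3": [112, 112, 16],
  "E4": [112, 112, 16],
  "E5": [112, 112, 32],
  "E6": [56, 56, 32],
  "E7": [56, 56, 32],
  "E8": [56, 56, 64],
  "E9": [28, 28, 64],
  "E10": [28, 28, 64],
  "E11": [28, 28, 128],
  "E12": [14, 14, 128],
  "E13": [14, 14, 128],
  "M": [14, 14, 256],
  "D1": [28, 28, 256],
  "D2": [28, 28, 256],
  "D3": [28, 28, 128],
  "D3c": [28, 28, 384],
  "D4": [28, 28, 128],
  "D5": [56, 56, 128],
  "D6": [56, 56, 128],
  "D7": [56, 56, 64],
  "D8": [56, 56, 192],
  "D9": [56, 56, 64],
  "D10": [112, 112, 64],
  "D11": [112, 112, 64],
  "D12": [112, 112, 32],
  "D13": [112, 112, 96],
  "D14": [112, 112, 32],
  "D15": [224, 224, 32],
  "D16": [224, 224, 32],
  "D17": [224, 224, 16],
  "D18": [224, 224, 48],
  "D19": [224, 224, 16],
  "F1": [224, 224, 128],
  "F2": [224, 224, 64],
  "F3": [224, 224, 32],
  "F4": [224, 224, 16],
  "F5": [224, 224, 240],
  "F6": [224, 224, 5],
  "F7": [224, 224, 5]
}
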