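# Controlled vocabulary: contraceptive method code -> outcome class.
# Modern methods are the provider-dependent / device / hormonal / permanent
# methods; traditional methods are behavioural.
modern:
  - female sterilization
  - male sterilization
  - iud
  - injectables
  - implants
  - pill
  - male condom
  - female condom
  - emergency contraception
  - other modern
traditional:
  - rhythm
  - withdrawal
  - lactational amenorrhea
  - other traditional
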