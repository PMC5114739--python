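{
  "bindea24.gmt": "2459dddad02c955f9d8b6125cf556c7e38b0936a6741e12fd8759df6a7ea773c",
  "angiogenesis.gmt": "ce8cb534f68d35537bdeda2b9de844a3c72b865ea638b8779ef6a8ba69a7c796"
}
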