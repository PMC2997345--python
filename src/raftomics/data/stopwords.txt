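a an and are as at be been but by for from has have in into is it its of on or
that the their there these this to was were which with we our they not no can
may also such more most other than then so its between during each both any
all its using used use study studies here show shown results data
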