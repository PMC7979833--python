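subfamily	lambda_base_nm
BacHR	537
XeR	565
ClR	530
PR	520
NaR	525
DTG	535
CyanDTEDTD	545
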