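br_position
82
83
85
86
89
90
93
96
115
118
119
122
138
141
142
145
148
182
185
186
189
208
212
215
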