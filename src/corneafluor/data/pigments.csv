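name,abs_excitation,abs_emission
purple,12.0,9.0
blue,11.0,8.5
black,7.5,6.5
brown,6.5,5.0
gray,6.0,5.3
amber,5.5,4.5
red,5.0,4.0
green,2.5,2.0
pink,2.0,1.5
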