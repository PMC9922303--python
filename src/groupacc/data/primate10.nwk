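(((((((human:0.0066,chimp:0.0068):0.0022,gorilla:0.0088):0.0097,orangutan:0.018):0.014,(macaque:0.0077,baboon:0.0075):0.030):0.023,marmoset:0.066):0.037,tarsier:0.14):0.010,(mouse_lemur:0.090,bushbaby:0.130):0.038);
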