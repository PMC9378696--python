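# Fitted activity-profile parameters for the 100 um-wide channel
# (exponential relaxation laws for L+, L- and lambda; lengths um, rates 1/s)
L_wall = 0.375
L_bulk = 3.70
l_plus = 5.05
l_minus = 10.8
lambda_wall = 0.237
lambda_bulk = 0.315
l_lambda = 8.20
y_col = 5.0
W = 50.0
a = 5.0
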