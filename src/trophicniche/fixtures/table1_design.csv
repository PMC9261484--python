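estuary,station,n,length_mean,length_sd
Slack,lower,6,419.3,138.5
Slack,middle,3,473.7,107.6
Slack,upper,11,395.2,85.7
Wimereux,lower,6,457.5,167.5
Wimereux,middle,6,424.7,102.1
Wimereux,upper,8,454.1,107.8
Liane,lower,2,509.5,94.0
Liane,middle,14,505.0,148.1
Liane,upper,4,560.5,167.9
Canche,lower,4,462.3,178.7
Canche,middle,7,377.7,84.5
Canche,upper,7,387.3,84.2
Authie,lower,5,510.6,126.9
Authie,middle,12,434.8,61.3
Authie,upper,4,364.0,89.1
Somme,lower,5,472.8,89.6
Somme,middle,4,499.3,262.8
Somme,upper,11,502.5,183.1
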