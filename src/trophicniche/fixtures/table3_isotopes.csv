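estuary,station,d13c_mean,d13c_sd,d15n_mean,d15n_sd,ta,seac,tp
Slack,lower,-22.3,1.3,16.3,0.5,2.8,2.5,4.0
Slack,middle,-23.6,1.7,16.4,1.2,0.1,0.5,3.7
Slack,upper,-24.7,2.5,15.6,0.7,8.7,5.2,4.0
Wimereux,lower,-24.0,1.3,16.4,0.7,2.9,2.9,4.3
Wimereux,middle,-25.0,1.2,15.5,1.7,4.1,4.4,3.6
Wimereux,upper,-25.3,1.2,16.0,1.6,5.8,5.2,4.0
Liane,lower,-26.0,0.1,18.5,0.5,,,5.1
Liane,middle,-26.8,0.7,16.9,1.6,8.1,4.0,4.0
Liane,upper,-26.4,0.6,15.7,1.9,0.9,1.6,4.0
Canche,lower,-23.1,5.5,14.3,0.8,10.4,19.4,3.7
Canche,middle,-22.5,1.8,14.5,0.9,4.7,3.8,3.3
Canche,upper,-23.8,2.5,13.4,0.6,5.0,4.0,3.3
Authie,lower,-18.5,2.2,15.1,0.3,1.7,2.1,3.7
Authie,middle,-22.8,2.6,14.6,0.6,4.1,2.5,3.5
Authie,upper,-28.2,1.0,12.8,0.5,0.7,1.5,3.2
Somme,lower,-17.3,0.8,15.5,0.4,0.8,1.0,3.2
Somme,middle,-21.4,6.5,14.8,0.7,10.8,20.4,3.3
Somme,upper,-28.0,5.0,14.3,1.2,37.3,20.5,2.8
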