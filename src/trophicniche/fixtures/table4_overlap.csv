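block,row,column,value,significant
sdoi,Slack,lower-middle,84,1
sdoi,Slack,lower-upper,62,1
sdoi,Slack,middle-upper,62,1
sdoi,Slack,Slack,100,0
sdoi,Slack,Wimereux,85,1
sdoi,Slack,Liane,67,1
sdoi,Slack,Canche,46,0
sdoi,Slack,Authie,19,0
sdoi,Slack,Somme,35,0
sdoi,Wimereux,lower-middle,61,1
sdoi,Wimereux,lower-upper,79,1
sdoi,Wimereux,middle-upper,45,0
sdoi,Wimereux,Wimereux,100,0
sdoi,Wimereux,Liane,72,1
sdoi,Wimereux,Canche,31,0
sdoi,Wimereux,Authie,4,0
sdoi,Wimereux,Somme,20,0
sdoi,Liane,lower-middle,18,0
sdoi,Liane,lower-upper,0,0
sdoi,Liane,middle-upper,66,1
sdoi,Liane,Liane,100,0
sdoi,Liane,Canche,30,0
sdoi,Liane,Authie,4,0
sdoi,Liane,Somme,18,0
sdoi,Canche,lower-middle,80,1
sdoi,Canche,lower-upper,88,1
sdoi,Canche,middle-upper,92,1
sdoi,Canche,Canche,100,0
sdoi,Canche,Authie,73,1
sdoi,Canche,Somme,83,1
sdoi,Authie,lower-middle,91,1
sdoi,Authie,lower-upper,86,1
sdoi,Authie,middle-upper,95,1
sdoi,Authie,Authie,100,0
sdoi,Authie,Somme,73,1
sdoi,Somme,lower-middle,17,0
sdoi,Somme,lower-upper,38,0
sdoi,Somme,middle-upper,79,1
sdoi,Somme,Somme,100,0
niche,Slack,lower-middle,18,0
niche,Slack,lower-upper,50,0
niche,Slack,middle-upper,27,0
niche,Slack,Slack,100,0
niche,Slack,Wimereux,66,1
niche,Slack,Liane,28,0
niche,Slack,Canche,38,0
niche,Slack,Authie,20,0
niche,Slack,Somme,54,0
niche,Wimereux,lower-middle,54,0
niche,Wimereux,lower-upper,56,0
niche,Wimereux,middle-upper,71,1
niche,Wimereux,Wimereux,100,0
niche,Wimereux,Liane,39,0
niche,Wimereux,Canche,33,0
niche,Wimereux,Authie,18,0
niche,Wimereux,Somme,41,0
niche,Liane,lower-middle,0,0
niche,Liane,lower-upper,0,0
niche,Liane,middle-upper,43,0
niche,Liane,Liane,100,0
niche,Liane,Canche,15,0
niche,Liane,Authie,8,0
niche,Liane,Somme,25,0
niche,Canche,lower-middle,44,0
niche,Canche,lower-upper,43,0
niche,Canche,middle-upper,48,0
niche,Canche,Canche,100,0
niche,Canche,Authie,72,1
niche,Canche,Somme,72,1
niche,Authie,lower-middle,36,0
niche,Authie,lower-upper,0,0
niche,Authie,middle-upper,14,0
niche,Authie,Authie,100,0
niche,Authie,Somme,62,1
niche,Somme,lower-middle,36,0
niche,Somme,lower-upper,0,0
niche,Somme,middle-upper,14,0
niche,Somme,Somme,100,0
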