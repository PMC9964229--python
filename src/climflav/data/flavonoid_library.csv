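formula,identity,flavonoid_class,lambda_max
C7H6O4,Protocatechuate,other,280
C16H18O9,Chlorogenic acid,other,285;325
C21H20O12,Isotrifolin,flavonol,283
C27H30O16,Rutin,flavonol,265;285;350
C21H20O12,Myricetin deoxyhexoside,flavonol,270;280;355
C27H30O16,Quercetin-3-rutinoside,flavonol,270;285;335
C21H20O11,Luteolin 6-C-glucoside,flavone,270;280;340
C21H20O11,Quercitrin,flavonol,240;265;350
C28H32O13,Genestein G 2,isoflavone,235;285
C30H26O14,Luteolin-4'-O-(6''-trans-caffeoyl)-beta-D-glucopyranoside,flavone,235;280;335
C22H38O12,Rhodioloside B,other,238;280
C28H46O8,Pladienolides F/Pladienolides G,other,245;280
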