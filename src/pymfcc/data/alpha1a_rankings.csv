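complex,residue,seq_number,energy,region
noradrenaline,ASP106,106,-8.32,ii
noradrenaline,VAL107,107,-4.50,i
noradrenaline,PHE288,288,-3.36,ii
noradrenaline,PHE312,312,-3.19,ii
noradrenaline,PHE289,289,-1.89,i
noradrenaline,CYS110,110,-1.58,i
noradrenaline,TYR316,316,-1.57,ii
noradrenaline,ILE178,178,-1.27,i
noradrenaline,SER188,188,-0.84,i
noradrenaline,TRP285,285,-0.82,ii
noradrenaline,MET292,292,1.40,i
oxymetazoline,PHE288,288,-7.83,i
oxymetazoline,ASP106,106,-6.88,i
oxymetazoline,PHE312,312,-5.93,i
oxymetazoline,VAL107,107,-4.68,ii
oxymetazoline,TRP285,285,-3.93,i
oxymetazoline,MET292,292,-3.08,iii
oxymetazoline,TYR184,184,-2.77,iii
oxymetazoline,PHE289,289,-2.54,ii
oxymetazoline,CYS110,110,-2.51,ii
oxymetazoline,TYR316,316,-2.33,i
oxymetazoline,ILE178,178,-1.99,ii
oxymetazoline,VAL185,185,-1.75,iii
oxymetazoline,SER188,188,-1.39,iii
oxymetazoline,GLU180,180,-1.37,iii
oxymetazoline,ALA189,189,-1.33,iii
tamsulosin,ASP106,106,-14.59,ii
tamsulosin,PHE312,312,-5.08,iii
tamsulosin,VAL107,107,-4.65,i
tamsulosin,ILE178,178,-3.65,ii
tamsulosin,PHE86,86,-3.39,iii
tamsulosin,TYR184,184,-3.03,i
tamsulosin,PHE288,288,-2.78,i
tamsulosin,TRP102,102,-2.13,iii
tamsulosin,TYR316,316,-1.83,i
tamsulosin,SER83,83,-1.54,iii
tamsulosin,MET292,292,-1.58,i
tamsulosin,LYS309,309,-1.48,iii
tamsulosin,GLU87,87,-1.43,iii
tamsulosin,SER188,188,-1.41,i
tamsulosin,CYS110,110,-1.38,i
tamsulosin,PHE308,308,-1.35,ii
tamsulosin,PHE289,289,-1.05,i
tamsulosin,CYS176,176,-0.75,iii
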