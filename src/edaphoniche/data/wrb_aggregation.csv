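detailed_code,dominant_class
ACh,Acrisols
ACf,Acrisols
ACp,Acrisols
ACu,Acrisols
ALh,Alisols
ALf,Alisols
ARo,Arenosols
ARa,Arenosols
CMd,Cambisols
CMe,Cambisols
CMu,Cambisols
FLe,Fluvisols
FLd,Fluvisols
FRh,Ferralsols
FRx,Ferralsols
FRg,Ferralsols
GLe,Gleysols
GLd,Gleysols
GLu,Gleysols
LPq,Leptosols
LPd,Leptosols
LXh,Lixisols
LXf,Lixisols
PTh,Plinthosols
PTu,Plinthosols
PZh,Podzols
PZg,Podzols
Acrisols,Acrisols
Ferralsols,Ferralsols
Gleysols,Gleysols
Podzols,Podzols
Cambisols,Cambisols
Plinthosols,Plinthosols
Alisols,Alisols
Arenosols,Arenosols
Lixisols,Lixisols
Fluvisols,Fluvisols
Leptosols,Leptosols
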