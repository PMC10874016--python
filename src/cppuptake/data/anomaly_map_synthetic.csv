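token,replacement,type,observed
a,A,d-a,1
c,C,d-c,1
d,D,d-d,1
e,E,d-e,1
f,F,d-f,1
g,G,d-g,1
h,H,d-h,1
i,I,d-i,1
k,K,d-k,1
l,L,d-l,1
m,M,d-m,1
n,N,d-n,1
p,P,d-p,1
q,Q,d-q,1
r,R,d-r,1
s,S,d-s,1
t,T,d-t,1
v,V,d-v,1
w,W,d-w,1
y,Y,d-y,1
U,C,selenocysteine,1
O,K,pyrrolysine,1
B,N,asx-ambiguous,1
Z,Q,glx-ambiguous,1
J,L,xle-ambiguous,1
X,A,unknown-residue,1
[Orn],K,ornithine,1
[Dab],K,diaminobutyric-acid,1
[Dap],K,diaminopropionic-acid,1
[MeLys],K,n-methyl-lysine,1
[AcLys],K,n-acetyl-lysine,1
[Cit],R,citrulline,1
[hArg],R,homoarginine,1
[Agb],R,norarginine,1
[Hyp],P,hydroxyproline,1
[Nle],L,norleucine,1
[hLeu],L,homoleucine,1
[Nva],V,norvaline,1
[Aib],A,aminoisobutyric-acid,1
[bAla],A,beta-alanine,1
[Abu],A,aminobutyric-acid,1
[Sar],G,sarcosine,1
[Pen],C,penicillamine,1
[hSer],S,homoserine,1
[pSer],S,phosphoserine,1
[Cha],F,cyclohexylalanine,1
[Dha],A,dehydroalanine,0
[Pip],P,pipecolic-acid,0
[Tle],V,tert-leucine,0
[Oic],P,octahydroindole-acid,0
[Chg],A,cyclohexylglycine,0
[Tic],F,tetrahydroisoquinoline-acid,0
[Bip],F,biphenylalanine,0
[hCys],C,homocysteine,0
[Hle],I,homoisoleucine,0
[Aad],E,aminoadipic-acid,0
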