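a
au
aux
avec
ce
ces
d
dans
de
des
du
elle
en
et
il
ils
je
l
la
le
les
leur
lui
ma
mais
me
meme
mes
moi
mon
ne
nos
notre
nous
on
ou
par
pas
pour
qu
que
qui
sa
se
ses
son
sur
ta
te
tes
toi
ton
tu
un
une
vos
votre
vous
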