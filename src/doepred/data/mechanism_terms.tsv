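raw_term	doe
agonist	activator
full agonist	activator
partial agonist	activator
activator	activator
stimulator	activator
opener	activator
inducer	activator
potentiator	activator
positive allosteric modulator	activator
pam	activator
releasing agent	activator
positive modulator	activator
antagonist	inhibitor
inverse agonist	inhibitor
inhibitor	inhibitor
blocker	inhibitor
channel blocker	inhibitor
gating inhibitor	inhibitor
suppressor	inhibitor
negative allosteric modulator	inhibitor
nam	inhibitor
allosteric antagonist	inhibitor
degrader	inhibitor
antisense inhibitor	inhibitor
binding agent	other
mixed agonist/antagonist	other
modulator	other
allosteric modulator	other
substrate	other
cofactor	other
chelator	other
cross-linking agent	other
gene replacement	other
protein replacement	other
proteolytic enzyme	other
vaccine antigen	other
unknown	other
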