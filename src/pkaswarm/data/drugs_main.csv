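name,pka_exp
ergotamine,6.3
nefazodone,6.5
nizatidine,6.59
trazodone,6.79
mirtazapine,7.3
clozapine,7.63
domperidone,7.9
tolamolol,7.9
lidocaine,7.94
naloxone,7.94
quinidine,8.05
diltiazem,8.06
nicotine,8.1
perphenazine,8.11
butorphanol,8.19
codeine,8.2
nebivolol,8.22
galanthamine,8.32
fentanyl,8.43
ranitidine,8.47
oxycodone,8.53
cocaine,8.7
meperidine,8.7
timolol,8.8
remoxipride,8.9
verapamil,8.92
rivastigmine,8.99
promethazine,9.1
mexiletine,9.15
levomepromazine,9.19
betaxolol,9.21
trimipramine,9.24
chlorpromazine,9.25
chlorpheniramine,9.26
propafenone,9.27
flecainide,9.3
citalopram,9.38
clomipramine,9.38
labetalol,9.4
amitriptyline,9.4
propranolol,9.45
sumatriptan,9.5
venlafaxine,9.5
azelastine,9.54
pindolol,9.54
bisoprolol,9.57
alprenolol,9.6
acebutolol,9.67
nadolol,9.67
metoprolol,9.7
tacrine,9.8
tolterodine,9.8
atropine,9.84
terbutaline,10
atomoxetine,10.1
nortriptyline,10.1
desipramine,10.23
maprotiline,10.5
amantadine,10.68
cimetidine,6.97
sufentanil,7.85
clonidine,8.05
morphine,8.18
risperidone,8.3
haloperidol,8.65
azithromycin,8.74
diphenhydramine,9.1
procainamide,9.24
promazine,9.28
imipramine,9.45
paroxetine,9.51
atenolol,9.6
sotalol,9.76
quinacrine,10.2
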