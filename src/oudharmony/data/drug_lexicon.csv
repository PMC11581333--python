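variant,canonical
heroin,heroin
heroine,heroin
herion,heroin
dope,heroin
smack,heroin
opium,heroin
opiates,opiates
opiate,opiates
oxycodone,oxycodone
oxy,oxycodone
oxys,oxycodone
oxycontin,oxycodone
percocet,oxycodone
percocets,oxycodone
perc,oxycodone
percs,oxycodone
roxy,oxycodone
hydrocodone,hydrocodone
vicodin,hydrocodone
vicoden,hydrocodone
lortab,hydrocodone
norco,hydrocodone
morphine,morphine
ms contin,morphine
codeine,codeine
codiene,codeine
hydromorphone,hydromorphone
dilaudid,hydromorphone
propoxyphene,propoxyphene
darvocet,propoxyphene
tramadol,tramadol
ultram,tramadol
fentanyl,fentanyl
fentanil,fentanyl
opioid analgesics,opioid_analgesic
opioid analgesic,opioid_analgesic
other opiates,opioid_analgesic
methadone,methadone
methadose,methadone
buprenorphine,buprenorphine
suboxone,buprenorphine
subutex,buprenorphine
bupe,buprenorphine
cocaine,cocaine
cocaine powder,cocaine
powder cocaine,cocaine
coke,cocaine
crack,crack
crack cocaine,crack
rock,crack
amphetamine,amphetamine
amphetamines,amphetamine
adderall,amphetamine
aderall,amphetamine
speed,amphetamine
methamphetamine,methamphetamine
meth,methamphetamine
crystal,methamphetamine
crystal meth,methamphetamine
ecstasy,mdma
extacy,mdma
ecstacy,mdma
exstacy,mdma
xtc,mdma
mdma,mdma
molly,mdma
benzodiazepine,benzodiazepine
benzodiazepines,benzodiazepine
benzo,benzodiazepine
benzos,benzodiazepine
xanax,benzodiazepine
zanax,benzodiazepine
valium,benzodiazepine
klonopin,benzodiazepine
ativan,benzodiazepine
barbiturate,barbiturate
barbiturates,barbiturate
phenobarbital,barbiturate
sedative,sedative
sedatives,sedative
sedative-hypnotic,sedative
ambien,sedative
thc,thc
marijuana,thc
marihuana,thc
weed,thc
cannabis,thc
cannabinoids,thc
pot,thc
hallucinogen,hallucinogen
hallucinogens,hallucinogen
lsd,hallucinogen
acid,hallucinogen
mushrooms,hallucinogen
shrooms,hallucinogen
pcp,pcp
inhalant,inhalant
inhalants,inhalant
whippits,inhalant
k2,k2
spice,k2
k2/spice,k2
kratom,kratom
alcohol,alcohol
etoh,alcohol
unknown,unknown
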