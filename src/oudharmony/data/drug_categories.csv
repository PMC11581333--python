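canonical,category
heroin,Heroin
opiates,Heroin
oxycodone,Opioid
hydrocodone,Opioid
morphine,Opioid
codeine,Opioid
hydromorphone,Opioid
propoxyphene,Opioid
tramadol,Opioid
fentanyl,Opioid
opioid_analgesic,Opioid
methadone,Methadone
buprenorphine,Buprenorphine
cocaine,Cocaine
crack,Cocaine
amphetamine,Amphetamine
methamphetamine,Amphetamine
mdma,MDMA
benzodiazepine,Benzodiazepine
barbiturate,Barbiturate
sedative,Sedatives
thc,THC
hallucinogen,Hallucinogen
pcp,Hallucinogen
inhalant,Inhalant
k2,K2
kratom,Kratom
alcohol,Alcohol
unknown,Unknown
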