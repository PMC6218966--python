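phrase	category	direction	kind
pas de	negation	forward	trigger
pas d'	negation	forward	trigger
n'a pas	negation	forward	trigger
ne presente pas	negation	forward	trigger
absence de	negation	forward	trigger
aucun	negation	forward	trigger
aucune	negation	forward	trigger
sans	negation	forward	trigger
est exclu	negation	backward	trigger
est exclue	negation	backward	trigger
est ecarte	negation	backward	trigger
sans doute	negation	forward	pseudo
sans difficulte	negation	forward	pseudo
antecedents de	temporality_historical	forward	trigger
antecedent de	temporality_historical	forward	trigger
antecedents familiaux de	temporality_historical	forward	trigger
histoire de	temporality_historical	forward	trigger
son pere	experiencer_other	forward	trigger
sa mere	experiencer_other	forward	trigger
son frere	experiencer_other	forward	trigger
sa soeur	experiencer_other	forward	trigger
famille	experiencer_other	forward	trigger
familial	experiencer_other	forward	trigger
familiale	experiencer_other	forward	trigger
si	temporality_hypothetical	forward	trigger
en cas de	temporality_hypothetical	forward	trigger
risque de	temporality_hypothetical	forward	trigger
mais			termination
cependant			termination
toutefois			termination
hormis			termination
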