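{
"metabolites":[
{
"id":"M1",
"name":"",
"compartment":"c"
},
{
"id":"M2",
"name":"",
"compartment":"c"
}
],
"reactions":[
{
"id":"EX_M1",
"name":"",
"metabolites":{
"M1":1.0
},
"lower_bound":0.0,
"upper_bound":10,
"gene_reaction_rule":""
},
{
"id":"R1",
"name":"",
"metabolites":{
"M1":-1.0,
"M2":1.0
},
"lower_bound":0.0,
"upper_bound":10.0,
"gene_reaction_rule":""
},
{
"id":"BIO",
"name":"",
"metabolites":{
"M2":-1.0
},
"lower_bound":0.0,
"upper_bound":1000000.0,
"gene_reaction_rule":"",
"objective_coefficient":1.0
}
],
"genes":[],
"id":"toy_chain",
"compartments":{
"c":""
},
"version":"1"
}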