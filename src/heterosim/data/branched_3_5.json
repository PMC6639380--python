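{
"metabolites":[
{
"id":"A",
"name":"",
"compartment":"c"
},
{
"id":"P1M1",
"name":"",
"compartment":"c"
},
{
"id":"Z",
"name":"",
"compartment":"c"
},
{
"id":"P2M1",
"name":"",
"compartment":"c"
}
],
"reactions":[
{
"id":"EX_A",
"name":"",
"metabolites":{
"A":1.0
},
"lower_bound":0.0,
"upper_bound":10,
"gene_reaction_rule":""
},
{
"id":"P1R1",
"name":"",
"metabolites":{
"A":-1.0,
"P1M1":1.0
},
"lower_bound":0.0,
"upper_bound":3.0,
"gene_reaction_rule":""
},
{
"id":"P1R2",
"name":"",
"metabolites":{
"P1M1":-1.0,
"Z":1.0
},
"lower_bound":0.0,
"upper_bound":3.0,
"gene_reaction_rule":""
},
{
"id":"P2R1",
"name":"",
"metabolites":{
"A":-1.0,
"P2M1":1.0
},
"lower_bound":0.0,
"upper_bound":5.0,
"gene_reaction_rule":""
},
{
"id":"P2R2",
"name":"",
"metabolites":{
"P2M1":-1.0,
"Z":1.0
},
"lower_bound":0.0,
"upper_bound":5.0,
"gene_reaction_rule":""
},
{
"id":"BIO",
"name":"",
"metabolites":{
"Z":-1.0
},
"lower_bound":0.0,
"upper_bound":1000000.0,
"gene_reaction_rule":"",
"objective_coefficient":1.0
}
],
"genes":[],
"id":"toy_branched",
"compartments":{
"c":""
},
"version":"1"
}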