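{
  "description": "Default clinical relation registry: 40 relation types; rag_use marks the 13 relations whose triples are eligible for retrieval-augmented context generation. count_hint records corpus-scale triple frequencies and is used only as a default sampling mix for synthetic graphs.",
  "relations": [
    {"name": "causes", "rag_use": true, "count_hint": 75927},
    {"name": "clinical course of", "rag_use": true, "count_hint": 7860},
    {"name": "definitional manifestation of", "rag_use": true, "count_hint": 59927},
    {"name": "diagnoses", "rag_use": true, "count_hint": 29128},
    {"name": "finding method of", "rag_use": true, "count_hint": 35077},
    {"name": "has adverse reaction", "rag_use": true, "count_hint": 4063753},
    {"name": "has contraindication", "rag_use": true, "count_hint": 925078},
    {"name": "has indication", "rag_use": true, "count_hint": 36778},
    {"name": "occurs in", "rag_use": true, "count_hint": 39128},
    {"name": "pathological process of", "rag_use": true, "count_hint": 46896},
    {"name": "predisposes", "rag_use": true, "count_hint": 15248},
    {"name": "prevents", "rag_use": true, "count_hint": 4846},
    {"name": "treats", "rag_use": true, "count_hint": 57028},
    {"name": "approach of", "rag_use": false, "count_hint": 4638},
    {"name": "associated etiologic finding of", "rag_use": false, "count_hint": 3258},
    {"name": "associated finding of", "rag_use": false, "count_hint": 26973},
    {"name": "associated with", "rag_use": false, "count_hint": 32384},
    {"name": "characterizes", "rag_use": false, "count_hint": 266},
    {"name": "component of", "rag_use": false, "count_hint": 4318},
    {"name": "direct morphology of", "rag_use": false, "count_hint": 48988},
    {"name": "direct procedure site of", "rag_use": false, "count_hint": 95600},
    {"name": "entire anatomy structure of", "rag_use": false, "count_hint": 29212},
    {"name": "finding site of", "rag_use": false, "count_hint": 443856},
    {"name": "focus of", "rag_use": false, "count_hint": 32154},
    {"name": "has part", "rag_use": false, "count_hint": 120694},
    {"name": "indirect morphology of", "rag_use": false, "count_hint": 3028},
    {"name": "indirect procedure site of", "rag_use": false, "count_hint": 31018},
    {"name": "inheres in", "rag_use": false, "count_hint": 386},
    {"name": "intent of", "rag_use": false, "count_hint": 45738},
    {"name": "interprets", "rag_use": false, "count_hint": 200184},
    {"name": "isa", "rag_use": false, "count_hint": 4826679},
    {"name": "method of", "rag_use": false, "count_hint": 620518},
    {"name": "occurs after", "rag_use": false, "count_hint": 32498},
    {"name": "occurs before", "rag_use": false, "count_hint": 32498},
    {"name": "part of", "rag_use": false, "count_hint": 4634},
    {"name": "procedure morphology of", "rag_use": false, "count_hint": 2152},
    {"name": "procedure site of", "rag_use": false, "count_hint": 156708},
    {"name": "surgical approach of", "rag_use": false, "count_hint": 1440},
    {"name": "temporally followed by", "rag_use": false, "count_hint": 6558},
    {"name": "temporally follows", "rag_use": false, "count_hint": 13686}
  ]
}
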