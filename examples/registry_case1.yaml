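# Worked-example federation, case 1: a clinical cohort service plus a
# curated question-answering service, both fixture-backed.
icees: {kind: fixture, case: 1}
robokop: {kind: fixture, case: 1}
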