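case_id	immunophenotype
C01	B-cell
C02	B-cell
C03	B-cell
C04	B-cell
C05	B-cell
C06	B-cell
C07	B-cell
C08	B-cell
C09	T-cell
C10	T-cell
C11	T-cell
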