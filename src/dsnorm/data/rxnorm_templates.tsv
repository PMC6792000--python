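# Template -> RxNorm term type, for the ten RxNorm codes applicable to
# single-ingredient supplement names.  Pack and multi-ingredient codes
# (GPCK, BPCK, MIN, PIN) are not applicable and never appear.
IN	IN
IN STR	SCDC
IN DF	SCDF
IN DFG	SCDG
IN STR DF	SCD
BN	BN
BN IN STR	SBDC
BN IN DF	SBDF
BN DFG	SBDG
BN IN STR DF	SBD
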