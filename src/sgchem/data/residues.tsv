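name	composition	mass	kind
hexose	C6H10O5	162.052824	glycosyl
deoxyhexose	C6H10O4	146.057909	glycosyl
pentose	C5H8O4	132.042259	glycosyl
malonylhexoside	C9H12O8	248.053218	glycosyl
hydroxylation	O	15.994915	biotransformation
saturation	H2	2.015650	biotransformation
acetylation	C2H2O	42.010565	biotransformation
water	H2O	18.010565	biotransformation
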