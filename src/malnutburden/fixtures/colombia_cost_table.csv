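cycle,direct,indirect
1,5696701.18,9064985.88
2,26443277.65,15305211.76
3,47409712.94,107372367.06
4,49369400.00,111833529.41
Total,128919089.41,243576094.12
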