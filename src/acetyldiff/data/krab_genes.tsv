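arsenic	shared	control
2610008E11RIK	BC003267	D10627
2810021J22RIK	CTCF	ZBTB25
5730577I03RIK	FIZ1	ZBTB43
5730601F06RIK	REPIN1	ZBTB7A
6430526N21RIK	ZBTB6	ZFP109
BC027344	ZFP26	ZFP160
BC049807	ZFP27	ZFP191
D330038O06RIK	ZFP341	ZFP12
E430018J23RIK	ZFP386	ZFP2
GM16386	ZFP398	ZFP212
MYNN	ZFP579	ZFP236
PRDM15	ZFP61	ZFP316
PRDM2	ZFP668	ZFP334
RBAK	ZFP867	ZFP407
ZBTB17		ZFP41
ZBTB48		ZFP422
ZBTB5		ZFP513
ZFAT		ZFP568
ZFP157		ZFP57
ZFP184		ZFP580
ZFP202		ZFP592
ZFP248		ZFP605
ZFP260		ZFP606
ZFP263		ZFP612
ZFP273		ZFP644
ZFP28		ZFP709
ZFP282		ZFP780B
ZFP317		ZFP786
ZFP335		ZFP788
ZFP358		ZFP821
ZFP382		ZFP827
ZFP397		ZFP846
ZFP454		ZFP868
ZFP566		ZFP873
ZFP583		ZFX
ZFP60		ZKSCAN2
ZFP62		
ZFP623		
ZFP628		
ZFP637		
ZFP655		
ZFP672		
ZFP68		
ZFP697		
ZFP748		
ZFP763		
ZFP773		
ZFP787		
ZFP788		
ZFP810		
ZFP867		
ZFP9		
ZFP94		
ZKSCAN6		
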