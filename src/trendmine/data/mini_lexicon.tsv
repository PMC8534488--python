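anger	-2.2
angry	-2.1
furious	-2.7
outraged	-2.6
rage	-2.5
disgusted	-2.2
resent	-1.8
infuriating	-2.4
hateful	-2.8
fear	-1.8
scared	-2.0
afraid	-1.9
worried	-1.6
terrified	-2.7
anxious	-1.5
panic	-2.3
frightening	-2.1
sadness	-2.0
sad	-1.8
grief	-2.4
heartbroken	-2.8
mourning	-2.2
tragic	-2.5
crying	-1.9
sorrow	-2.1
devastated	-2.9
joy	2.4
happy	2.0
delighted	2.2
wonderful	2.3
great	1.9
awesome	2.6
thrilled	2.4
celebrate	1.8
hopefulness	1.9
hopeful	1.9
hope	1.5
optimistic	2.0
encouraging	1.8
promising	1.7
reassuring	1.6
confident	1.8
uplifting	2.1
good	1.9
bad	-2.5
terrible	-2.9
awful	-2.7
love	3.0
hate	-2.7
safe	1.4
effective	1.3
dangerous	-2.2
failure	-2.1
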