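OF	THE	4200
IN	THE	3900
TO	THE	2500
ON	THE	1800
TO	BE	1200
IT	IS	1100
IT	WAS	900
THIS	IS	760
WANT	TO	700
GO	TO	640
I	DO	520
DO	IT	500
DO	NOT	450
JUST	BE	420
THAT	WAS	410
DO	YOU	400
JUST	ONE	380
JUST	LIKE	350
LIKE	TO	340
YOU	CAN	310
I	WANT	300
WAS	NOT	280
A	NEW	240
DO	THE	200
NOT	LIKE	130
JUST	DO	120
WILL	GO	120
THE	DOG	90
THE	BOOK	85
THE	TRAIN	60
NEW	WORLD	45
MY	MOTHER	40
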