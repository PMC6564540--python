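THE	9000
OF	4500
AND	3000
TO	2250
IT	2200
A	1800
IN	1500
IS	1285
YOU	1000
THAT	900
HE	818
WAS	750
DO	700
FOR	692
ON	642
ARE	600
WITH	562
AS	529
I	500
HIS	473
THEY	450
BE	428
AT	409
ONE	391
HAVE	375
THIS	360
FROM	346
OR	333
HAD	321
BY	310
JUST	300
NOT	300
WORD	290
BUT	281
WHAT	272
SOME	264
WE	257
CAN	250
OUT	243
OTHER	236
WERE	230
ALL	225
THERE	219
WHEN	214
UP	209
USE	204
YOUR	200
HOW	195
SAID	191
AN	187
EACH	183
SHE	180
WHICH	176
THEIR	169
TIME	166
IF	163
WILL	160
WAY	157
ABOUT	155
MANY	152
JOB	150
THEN	150
THEM	147
WRITE	145
WOULD	142
LIKE	140
SO	138
THESE	136
HER	134
LONG	132
MAKE	130
THING	128
SEE	126
HIM	125
TWO	123
HAS	121
LOOK	120
MORE	118
DAY	116
COULD	115
GO	113
COME	112
DID	111
NUMBER	109
SOUND	108
NO	107
MOST	105
PEOPLE	104
MY	103
OVER	102
KNOW	101
WATER	100
THAN	98
CALL	97
FIRST	96
WHO	95
MAY	94
DOWN	93
SIDE	92
BEEN	91
FIND	90
NOW	90
ANY	89
NEW	88
WORK	87
PART	86
TAKE	85
GET	84
PLACE	84
MADE	83
LIVE	82
AFTER	81
WHERE	81
BACK	80
JUMP	80
LITTLE	79
ONLY	78
ROUND	78
MAN	77
CAME	76
YEAR	76
EVERY	75
SHOW	75
GOOD	74
GIVE	73
ME	73
OUR	72
UNDER	72
NAME	71
THROUGH	70
VERY	70
FORM	69
GREAT	68
SENTENCE	68
SAY	67
THINK	67
HELP	66
LOW	66
DIFFER	65
LINE	65
CAUSE	64
TURN	64
MEAN	63
MUCH	63
BEFORE	62
MOVE	62
RIGHT	62
BOY	61
OLD	61
JOIN	60
SAME	60
TELL	60
TOO	60
DOES	59
SET	59
AIR	58
THREE	58
WANT	58
ALSO	57
WELL	57
END	56
PLAY	56
SMALL	56
HOME	55
PUT	55
READ	55
HAND	54
LARGE	54
PORT	54
ADD	53
EVEN	53
SPELL	53
BIG	52
HERE	52
LAND	52
MUST	52
FOLLOW	51
HIGH	51
SUCH	51
ACT	50
ASK	50
MEN	50
WHY	50
CHANGE	49
LIGHT	49
WENT	49
HOUSE	48
KIND	48
NEED	48
OFF	48
AGAIN	47
PICTURE	47
TRY	47
US	47
ANIMAL	46
MOTHER	46
POINT	46
WORLD	46
BUILD	45
EARTH	45
FATHER	45
NEAR	45
SELF	45
BRAIN	44
TRAIN	44
BOOK	43
CAT	43
DOG	43
MUSIC	43
SCHOOL	42
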