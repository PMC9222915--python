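>allele_1
SSLSNKTIHNNNNYKYNYNNNNYNNNNYNNNYNNNCKKLYYNINYIEQI
>allele_2
SSLSNNYNYNNYNNNYKPLYYNINYIEQI
>allele_3
SSLSNNYNSNSYNNYNNNYKKLQYYNIINIEQI
>allele_4
SSLSNNTIHNNNYKYNYNNNYNNYNNYKKLYYNINYIEQI
>allele_5
SSLSNKTIHNNNNYKYNYNNNYNNNNNYSKKLYYNINYIEQI
>allele_6
SSLSNNYNYSNYNNYNNYNNNYNNYKKLYYNINYIEQI
>allele_7
SSLSKNTIHNNNYKYNYNNNNNYNNNYKKLQYYNINYIEQI
>allele_8
SSLSNSCNYSNNYYNKKLYYNIINIEQI
>allele_9
SSLSNKTIHNNNNYKYNYNNKYNYNNNNYNKKLYYKNYIINIEQI
>allele_10
SSLSNNYNYSNYNNYNNNYNNYKKLYYNINYIEQI
>allele_11
SSLSNNYISNISNYNNNNNSKKLYYNINYIEQI
>allele_12
SSLSKNTIHNNNYKYNYNNNNYNNSKKLYYNINYIEQI
>allele_13
SSLSNKTIHNNNNYKYNYNNNNYKNYNNYKKLYYNINYIEQI
>allele_14
SSLSNKTIHNNNNYNNYKKLYYNIINIEQI
>allele_15
SSLSNNTIHNNNYKYNNYNNYNKKLYYNIINIEQI
>allele_16
SSLSNKTIHNNNNYNNNNYNNYKKLYYNINYIEQI
>allele_17
SSLSNNTIHNNNNYNKKLYYNIINIEQI
>allele_18
SSLSNKTIHNNNNYKYNYNNNCKKLYYNINYIEQI
>allele_19
SSLSNNYKYSNYNNYNNNYNNNYNNNYNNNYKKLYKNYIINIEQI
>allele_20
SSLSNNYNSNNYNKYNYNNSKKLYYNINYIEQI
>allele_21
SSLSNKTIHNNNNYNNNNYNNYKKLYYNIINIEQI
>allele_22
SSLSNNYKYSNYNNYNNNYNNYNNNYNNNYKKLYYNINYIEQI
>allele_23
SSLSNHYNYNNNKYNNYNNDYKKLYYNINYIEQI
>allele_24
SSLSNKTIHNNNNYKYNYKNYNNSKKLYYNVINIEQI
>allele_25
SSLSNKTIHNNNNYNNYKKLYYNINYIEQI
>allele_26
SSLSNKTIHNNNKYNYNKYNYNNNNYNNYKKLYYNINYIEQI
>allele_27
SSLSNNYNYNNNNYNNYNNNYNNNYNKKLYYNIINIEQI
>allele_28
SSLSNKTIHNNNNYKYNYNNNNYNNNYNNNCKKLYYNIINIEQI
>allele_29
SSLSNNYNYNNNNYNNNYNKKLYYNINYIEQI
>allele_30
SSLSNNYNSNNYYNYNNNKKLYYKNYIINIEQI
>allele_31
SSLSNKTIHNNNNYKYNYNNKYNYNNNNYNNNNYNKKLYYKNYIINIEQI
>allele_32
SSLSNSCNYSNNYNNNYNNTKKLYYNINYIEQI
>allele_33
SSLSNKTIHNNNNYKNYNYKKLYYNIINIEQI
>allele_34
SSLSNNYNYSNYNNNNYKQLCYNINYIEQI
>allele_35
SSLSNNYNYSNYNNYNNYNNNYNNYNNNYNNYKKLYYNINYIEQI
>allele_36
SSLSNNYNSNSYNNYNNNYYNNKKLQYYNINYIEQI
>allele_37
SSLSNKTIHNNNNYNNNNYNNYNNNNYNNYKKLYYNIINIEQI
>allele_38
SSLSSNYNSNNYNNYNNYKQLCYNINYIEQI
>allele_39
SSLSNNYNYNNNKYNYNNNNYKQLCYNINYIEQI
>allele_40
SSLSNKTIHNNNNYNNNNYNNYNNNNYNNYKKLYYNINYIEQI
>allele_41
SSLSNNYKYSNYNNYNNNNYNNNNYNNNSKKLYYNIINIEQI
>allele_42
SSLSNKTIHNNNNYNNNNYKKLQYYNINYIEQI
>allele_43
SSLSNNYNYNNNNYNNYNNNYNNNYNKKLYYNINYIEQI
>allele_44
SSLSNKTIHNNNYKYNYYNNNNYKKLQYYNIINIEQI
>allele_45
SSLSNNYNYNNNNYNNYNNYNNYNNNYNKKLYYNINYIEQI
>allele_46
SSLSNNYKYSNYNNYNNYNKKLYYKNYIINIEQI
>allele_47
SSLSNNYNYNNNNYNNYNNYNNNYNNNYNKKLYYNINYIEQI
>allele_48
SSLSNNYKYSNYNNNNYNNNSKKLYYNINYIEQI
>allele_49
SSLSNKTIHNNNNYNNNNYNKKLYYNINYIEQI
>allele_50
SSLSNKTIHNNNNYKYNYNNNNYNNNYNNYKKLYYNINYIEQI
>allele_51
SSLSNKTIHNNNNYKNYNNYKNYNNYKKLYYNINYIEQI
>allele_52
SSLSNKTIHNNNNYKYNYNNNNYNNNNYNKKLYYKNYIINIEQI
>allele_53
SSLSNNTIHNNNYKYNYNNKYNYNNKKLYYNIINIEQI
>allele_54
SSLSNKTIHNNNNYKYNYNNNNYNNNNYNNNYNNNCKKLYYNIINIEQI
>allele_55
SSLSNNYNSNSYNNNYNNNYYNKKLQYYNINYIEQI
>allele_56
SSLSNNYKYSNYNNYNNYNNNNYNNYNNYNNKKLYYNIINIEQI
>allele_57
SSLSNKTIHNNNNYKKLYYNINYIEQI
>allele_58
SSLSNNYNYSNYNNYNNYKKLYYNINYIEQI
>allele_59
SSLSNNTIHNNNYKYNYNNNNYNNNNYNKKLYYNIINIEQI
>allele_60
SSLSNNYNYSNYNNYNNNNNYNNYKKLYYNINYIEQI
>allele_61
SSLSNNYKYSNYNNYNNNYNNYNNNYKKLYYNINYIEQI
>allele_62
SSLSSSCNYSNNYNNYYNNNKKLYYNIINIEQI
>allele_63
SSLSNKTIHNNNKYNYNNNYNNNCKKLYYNINYIEQI
>allele_64
SSLSNNRNSNNYNNYNYKKLYYNINYIEQI
>allele_65
SSLSNNYNYSNYNNYNNNYNNNYNNNDYKKLYYKNYIINIEQI
>allele_66
SSLSNNYNYSNYNNYNNNNYNNYKKLYYNINYIEQI
>allele_67
SSLSNNYNYSNNYNNYYNNNNNYNNYKKLYYNIINIEQI
>allele_68
SSLSKNTIHNNNYNNSKKLYYNIINIEQI
>allele_69
SSLSNKTIHNNNNYNNNYNNNCKKLYYNIINIEQI
>allele_70
SSLSNKTIHNNNNYNNNNYNNNNYNNNNYKKLQYYNINYIEQI
>allele_71
SSLSNNYKYSNYNNYNNNNYKKLQYYNINYIEQI
>allele_72
SSLSNKTIHNNNNYKYNYNNNNYKPYYNINYIEQI
>allele_73
SSLSNKTIHNNNNYKYNYNNNYKKLYYKNYIINIEQI
>allele_74
SSLSNKTIHNNNNYKYNYNNNYNNNSKKLQYYYNINYIEQI
>allele_75
SSLSNKTIHNNNYKYNYNNKHNYNKLYYNINYIEQI
>allele_76
SSLSNNYKYSNYNNYNNYNNNSKKLYKNYIINIEQI
>allele_77
SSLSNKTIHNNNNYNNNNYNNYNNNNYNYKKLYYNINYIEQI
>allele_78
SSLSNKTIHNNNNYKYNYNNNYNNNSKKLYYNINYIEQI
>allele_79
SSLSNNYNYSNYNNYNNNYNNYNKKLYYNINYIEQI
>allele_80
SSLSNKTIHNNNNYKNYNNYKNYNNYKNYNNYKKLYYNINYIEQI
>allele_81
SSLSNNYNYNNYNNTNNINKQLYYNINYIEQI
>allele_82
SSLSNNYSYNNYNNNNYNKKLYYNINYIEQI
>allele_83
SSLSNNYNYNNNNYNNYNNNYNKKLYYNINYIEQI
>allele_84
SSLSNNYNYSNYNNYNNNNNYNNNNYNYKKLYYNINYIEQI
>allele_85
SSLSNKTIHNNNNNYNNYNKKLYYNIINIEQI
>allele_86
SSLSNNTIHNNNNYKYNYNNNYNNYNNYNNKKLYYNIINIEQI
>allele_87
SSLSTNTIHNNNNYKYNYNNNYNNYNNKKLYYNINYIEQI
>allele_88
SSLSNNYISNISNYNNNNNYNKKLYYNINYIEQI
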