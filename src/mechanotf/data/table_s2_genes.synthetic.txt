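NR4A1
CEBPD
KLF9
ZNF331
IRF1
NR6A1
SYNG001
SYNG002
SYNG003
SYNG004
SYNG005
SYNG006
SYNG007
SYNG008
SYNG009
SYNG010
SYNG011
SYNG012
SYNG013
SYNG014
SYNG015
SYNG016
SYNG017
SYNG018
SYNG019
SYNG020
SYNG021
SYNG022
SYNG023
SYNG024
SYNG025
SYNG026
SYNG027
SYNG028
SYNG029
SYNG030
SYNG031
SYNG032
SYNG033
SYNG034
SYNG035
SYNG036
SYNG037
SYNG038
SYNG039
SYNG040
SYNG041
SYNG042
SYNG043
SYNG044
SYNG045
SYNG046
SYNG047
SYNG048
SYNG049
SYNG050
SYNG051
SYNG052
SYNG053
SYNG054
SYNG055
SYNG056
SYNG057
SYNG058
SYNG059
SYNG060
SYNG061
SYNG062
SYNG063
SYNG064
SYNG065
SYNG066
SYNG067
SYNG068
SYNG069
SYNG070
SYNG071
SYNG072
SYNG073
SYNG074
SYNG075
SYNG076
SYNG077
SYNG078
SYNG079
SYNG080
SYNG081
SYNG082
SYNG083
SYNG084
SYNG085
SYNG086
SYNG087
SYNG088
SYNG089
SYNG090
SYNG091
SYNG092
SYNG093
SYNG094
SYNG095
SYNG096
SYNG097
SYNG098
SYNG099
SYNG100
SYNG101
SYNG102
SYNG103
SYNG104
SYNG105
SYNG106
SYNG107
SYNG108
SYNG109
SYNG110
SYNG111
SYNG112
SYNG113
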