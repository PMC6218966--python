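# UMLS Semantic Groups -> Semantic Types (TUIs). One TUI belongs to one group.
ACTI	T052
ACTI	T053
ACTI	T056
ACTI	T051
ACTI	T064
ACTI	T055
ACTI	T066
ACTI	T057
ACTI	T054
ANAT	T017
ANAT	T029
ANAT	T023
ANAT	T030
ANAT	T031
ANAT	T022
ANAT	T025
ANAT	T026
ANAT	T018
ANAT	T021
ANAT	T024
CHEM	T116
CHEM	T195
CHEM	T123
CHEM	T122
CHEM	T103
CHEM	T120
CHEM	T104
CHEM	T200
CHEM	T196
CHEM	T126
CHEM	T131
CHEM	T125
CHEM	T129
CHEM	T130
CHEM	T197
CHEM	T114
CHEM	T109
CHEM	T121
CHEM	T192
CHEM	T127
CONC	T185
CONC	T077
CONC	T169
CONC	T102
CONC	T078
CONC	T170
CONC	T171
CONC	T080
CONC	T081
CONC	T089
CONC	T082
CONC	T079
DEVI	T203
DEVI	T074
DEVI	T075
DISO	T020
DISO	T190
DISO	T049
DISO	T019
DISO	T047
DISO	T050
DISO	T033
DISO	T037
DISO	T048
DISO	T191
DISO	T046
DISO	T184
GENE	T087
GENE	T088
GENE	T028
GENE	T085
GENE	T086
GEOG	T083
LIVB	T100
LIVB	T011
LIVB	T008
LIVB	T194
LIVB	T007
LIVB	T012
LIVB	T204
LIVB	T099
LIVB	T013
LIVB	T004
LIVB	T096
LIVB	T016
LIVB	T015
LIVB	T001
LIVB	T101
LIVB	T098
LIVB	T097
LIVB	T014
LIVB	T010
LIVB	T005
OBJC	T071
OBJC	T168
OBJC	T073
OBJC	T072
OBJC	T167
OCCU	T091
OCCU	T090
ORGA	T093
ORGA	T092
ORGA	T094
ORGA	T095
PHEN	T038
PHEN	T069
PHEN	T068
PHEN	T034
PHEN	T070
PHEN	T067
PHYS	T043
PHYS	T201
PHYS	T045
PHYS	T041
PHYS	T044
PHYS	T032
PHYS	T040
PHYS	T042
PHYS	T039
PROC	T060
PROC	T065
PROC	T058
PROC	T059
PROC	T063
PROC	T062
PROC	T061
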