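"""The six structural-variant categories.

Category definitions (copy number of the reference genotype vs. the test
panel):

==================  =========  =============================================
category            reference  test-panel pattern
==================  =========  =============================================
DownCNV/PAV         1          zero copies in >=1 line, none above 1
UpPAV               0          a single group of >=1 copies in >=1 line
UpPAV+UpCNV         0          multiple distinct groups of >=1 copies
UpCNV+DownCNV       1          zero copies in >=1 line AND >1 in >=1 line
UpCNV               1          a single group of >1 copies, no zeros
Multi-Allelic UpCNV 1          multiple distinct groups of >1 copies
==================  =========  =============================================
"""

DOWN_CNV_PAV = "DownCNV/PAV"
UP_PAV = "UpPAV"
UP_PAV_UP_CNV = "UpPAV+UpCNV"
UP_CNV_DOWN_CNV = "UpCNV+DownCNV"
UP_CNV = "UpCNV"
MULTI_ALLELIC_UP_CNV = "Multi-Allelic UpCNV"

#: canonical reporting order (matches the summary-table layout)
CATEGORIES = (
    DOWN_CNV_PAV,
    UP_PAV,
    UP_PAV_UP_CNV,
    UP_CNV_DOWN_CNV,
    UP_CNV,
    MULTI_ALLELIC_UP_CNV,
)

#: categories exclusively associated with Up (gain / presence-in-test) regions
UP_EXCLUSIVE_CATEGORIES = (UP_PAV, UP_PAV_UP_CNV, UP_CNV, MULTI_ALLELIC_UP_CNV)

#: categories whose reference copy number is zero
REF_ABSENT_CATEGORIES = (UP_PAV, UP_PAV_UP_CNV)

#: subclasses entering the Down rSFS
DOWN_SFS_CATEGORIES = (DOWN_CNV_PAV,)

#: subclasses entering the Up rSFS
UP_SFS_CATEGORIES = (UP_CNV, MULTI_ALLELIC_UP_CNV)
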