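"""Combine both strands into the -4..+4 convergence/divergence matrix.

Pairs natural-science and community-perception scores per site x habitat
x direction, subtracts CP from NS, and classifies each difference.
"""

from ecoconverge import HarmonizedScore, build_matrix
from ecoconverge.convergence import matrix_to_frame


def ns(site, habitat, direction, score):
    return HarmonizedScore("NS", site, habitat, direction, score, n=9)


def cp(site, habitat, direction, score):
    return HarmonizedScore("CP", site, habitat, direction, score, n=250,
                           raw_median=float(score))


matrix = build_matrix(
    ns_scores=[
        ns("hoi_an", "coral", "past", 1),
        ns("hoi_an", "mangrove", "past", -2),
        ns("puerto", "fisheries", "past", -1),
        ns("puerto", "fisheries", "future", 0),
    ],
    cp_scores=[
        cp("hoi_an", "coral", "past", 1),
        cp("hoi_an", "mangrove", "past", 2),
        cp("puerto", "fisheries", "past", -1),
        cp("puerto", "fisheries", "future", -1),
        cp("puerto", "seagrass", "past", 0),  # no NS partner: stays blank
    ],
)
print(matrix_to_frame(matrix).to_string(index=False))
print("\nd = NS - CP: 0 is full convergence; positive d means the "
      "measurements look rosier\nthan the community's perception "
      "(negative the reverse). The unpaired seagrass row\nis kept as a "
      "missing cell rather than dropped.")
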