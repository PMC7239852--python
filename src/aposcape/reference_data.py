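"""Published per-population reference values for *Paspalum intermedium*.

These tables transcribe the population-level summary statistics printed in the
original field survey of facultative apomictic *P. intermedium* (collection
codes ``Hojs402``–``Hojs478``).  They are *inputs*: the survey released no raw
ovule or seed counts, only population-level proportions, so the printed
expected/observed seed proportions are the finest-grained data available for
re-deriving pathway efficiencies and competition statistics.

``POLYPLOID_PATHWAY_TABLE`` holds, for each polyploid population, the expected
and observed proportions of sexual and apomictic seeds together with the
printed pathway-efficiency values.  Expected proportions derive from
ovule-stage embryo-sac frequencies under the independence null (mixed ovules
credited half to each pathway); observed proportions come from the flow
cytometric seed screen.

``OVERALL_FITNESS`` holds the cytotype-level fecundity and germinability
components and the printed maternal-fitness product.
"""

from __future__ import annotations

import pandas as pd

# columns: expected/observed sexual proportion, expected/observed apomictic
# proportion, printed sexual and apomictic efficiencies (3 decimals).
_PATHWAY_ROWS = [
    # code        exp_s  obs_s  exp_a  obs_a  eff_s  eff_a
    ("Hojs402", 0.173, 0.169, 0.827, 0.831, 0.981, 1.004),
    ("Hojs403", 0.415, 0.068, 0.585, 0.932, 0.164, 1.594),
    ("Hojs404", 0.387, 0.076, 0.613, 0.924, 0.196, 1.507),
    ("Hojs405", 0.401, 0.100, 0.599, 0.900, 0.249, 1.503),
    ("Hojs409", 0.307, 0.061, 0.693, 0.939, 0.198, 1.355),
    ("Hojs410", 0.356, 0.263, 0.644, 0.737, 0.740, 1.144),
    ("Hojs414", 0.093, 0.067, 0.907, 0.933, 0.719, 1.029),
    ("Hojs415", 0.318, 0.143, 0.682, 0.857, 0.450, 1.256),
    ("Hojs424", 0.376, 0.129, 0.624, 0.871, 0.342, 1.397),
    ("Hojs445", 0.448, 0.096, 0.552, 0.904, 0.215, 1.636),
    ("Hojs453", 0.469, 0.167, 0.531, 0.833, 0.355, 1.569),
    ("Hojs455", 0.429, 0.225, 0.571, 0.775, 0.525, 1.358),
    ("Hojs456", 0.463, 0.235, 0.537, 0.765, 0.509, 1.423),
    ("Hojs465", 0.500, 0.076, 0.500, 0.924, 0.152, 1.848),
    ("Hojs470", 0.678, 0.333, 0.322, 0.667, 0.491, 2.072),
    ("Hojs475", 0.400, 0.184, 0.600, 0.816, 0.459, 1.361),
    ("Hojs478", 0.063, 0.037, 0.938, 0.963, 0.593, 1.027),
    ("Hojs471", 0.407, 0.172, 0.593, 0.828, 0.423, 1.396),
]

POLYPLOID_PATHWAY_TABLE = pd.DataFrame(
    _PATHWAY_ROWS,
    columns=[
        "population_id",
        "exp_sexual",
        "obs_sexual",
        "exp_apomictic",
        "obs_apomictic",
        "eff_sexual",
        "eff_apomictic",
    ],
).set_index("population_id")

# Populations whose printed efficiencies are reproduced exactly (3 decimals,
# both pathways) by obs/exp on the printed proportions.  The remaining rows
# carry sub-millesimal input-rounding noise; two rows (Hojs402, Hojs478
# sexual component) deviate by up to 0.006 because the original ratios were
# taken on unrounded proportions.
EXACT_EFFICIENCY_ROWS = ("Hojs404", "Hojs405", "Hojs465", "Hojs471")

# Rows whose *sexual* (resp. *apomictic*) efficiency value alone reproduces
# the printed value exactly at 3 decimals.
EXACT_SEXUAL_EFFICIENCY_ROWS = (
    "Hojs403", "Hojs404", "Hojs405", "Hojs415", "Hojs465", "Hojs470", "Hojs471",
)
EXACT_APOMICTIC_EFFICIENCY_ROWS = (
    "Hojs404", "Hojs405", "Hojs409", "Hojs410", "Hojs414", "Hojs453",
    "Hojs465", "Hojs471", "Hojs478",
)

# Cytotype-level fitness components: fecundity proportion, germinability
# proportion and the printed maternal fitness (product of unrounded inputs).
OVERALL_FITNESS = pd.DataFrame(
    [
        ("2x", 0.37, 0.739, 0.276),
        ("4x", 0.17, 0.791, 0.135),
    ],
    columns=["cytotype", "fecundity", "germinability", "fitness"],
).set_index("cytotype")

# Pooled polyploid seed-stage null: expected vs observed sexual percentage.
POOLED_EXPECTED_SEXUAL = 0.382
POOLED_OBSERVED_SEXUAL = 0.153
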