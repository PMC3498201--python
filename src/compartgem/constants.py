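"""Model-wide conventions: compartments, interfaces, currency species, topology.

These defaults encode the conventions of a nine-compartment, surface-oriented
zebrafish genome-scale reconstruction.  Everything here is overridable at the
API and CLI level; the constants are the starting point, not a straitjacket.
"""

from __future__ import annotations

#: Compartment token -> human-readable name.  Tokens follow the common GEM
#: suffix convention (``atp[c]`` is cytoplasmic ATP).
COMPARTMENT_NAMES: dict[str, str] = {
    "c": "cytoplasm",
    "e": "extracellular space",
    "r": "endoplasmic reticulum",
    "g": "Golgi apparatus",
    "l": "lysosome",
    "m": "mitochondria",
    "i": "mitochondrial intermembrane space",
    "n": "nucleus",
    "x": "peroxisome",
}

#: The single extracellular compartment token.
EXTRACELLULAR = "e"

#: The thirteen ubiquitous cofactors removed from graph analyses (but never
#: from flux balance analysis): protons, water, the adenylate pool, phosphate
#: pools, sodium, coenzyme A, oxygen and the NAD(P) redox pairs.
CURRENCY_METABOLITES: frozenset[str] = frozenset(
    {
        "h",
        "h2o",
        "atp",
        "adp",
        "pi",
        "ppi",
        "na1",
        "coa",
        "o2",
        "nad",
        "nadh",
        "nadp",
        "nadph",
    }
)

#: Species allowed to exchange freely with the environment: their exchange
#: fluxes are excluded from the minimise-uptake objective.
FREE_EXCHANGE: frozenset[str] = frozenset({"o2", "h2o", "co2"})

#: Nutrient uptake categories (dietary requirement of a freshwater fish) and
#: the number of uptake exchange reactions in each.
NUTRIENT_UPTAKE_CATEGORIES: dict[str, int] = {
    "essential_amino_acids": 10,
    "lipids": 2,
    "carbohydrates": 9,
    "macrominerals": 6,
    "microminerals": 6,
    "fat_soluble_vitamins": 4,
    "water_soluble_vitamins": 10,
}

#: Number of biomass components in the full reconstruction.
BIOMASS_COMPONENT_COUNT = 42

#: Physical adjacency of compartments (unordered pairs).  The extracellular
#: space touches only the cytoplasm; every organelle touches the cytoplasm
#: except the mitochondrial matrix, which is reached through the intermembrane
#: space; vesicular routes join ER-Golgi, Golgi-lysosome and Golgi-plasma
#: membrane.
DEFAULT_TOPOLOGY: frozenset[frozenset[str]] = frozenset(
    frozenset(edge)
    for edge in [
        ("e", "c"),
        ("c", "r"),
        ("c", "g"),
        ("c", "l"),
        ("c", "n"),
        ("c", "x"),
        ("c", "i"),
        ("i", "m"),
        # vesicular transport
        ("r", "g"),
        ("g", "l"),
        ("g", "e"),
    ]
)

#: Default interface list: one lumen (soluble) interface per compartment plus
#: nine membrane faces.  ``(membrane_of, facing)``: the active site of an
#: enzyme on that face draws on the ``facing`` compartment's metabolite pool.
#: The full reconstruction declares 18 interfaces; this list reproduces that
#: count and is overridable from configuration.
DEFAULT_INTERFACES: list[tuple[str, str, str, bool]] = [
    # (id, membrane_of, facing, is_lumen)
    ("c_lumen", "c", "c", True),
    ("e_lumen", "e", "e", True),
    ("r_lumen", "r", "r", True),
    ("g_lumen", "g", "g", True),
    ("l_lumen", "l", "l", True),
    ("m_lumen", "m", "m", True),
    ("i_lumen", "i", "i", True),
    ("n_lumen", "n", "n", True),
    ("x_lumen", "x", "x", True),
    ("pm_c", "c", "e", False),  # plasma membrane, exofacial side
    ("er_c", "r", "c", False),  # ER membrane, cytosolic side
    ("golgi_c", "g", "c", False),
    ("lyso_c", "l", "c", False),
    ("nuc_c", "n", "c", False),
    ("perox_c", "x", "c", False),
    ("mom_c", "i", "c", False),  # mitochondrial outer membrane, cytosolic side
    ("mim_i", "m", "i", False),  # inner membrane, intermembrane side
    ("mim_m", "i", "m", False),  # inner membrane, matrix side
]

#: Default magnitude of reversible flux bounds (arbitrary flux units).
DEFAULT_BOUND = 1000.0

#: Flux-activity threshold: a reaction "carries flux" iff |v| >= EPSILON.
EPSILON = 1e-6

#: Default fixed biomass synthesis rate for the minimise-uptake optimum.
DEFAULT_BIOMASS_RATE = 1.0
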