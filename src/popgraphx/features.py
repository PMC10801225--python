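"""Feature registry for the multimodal dementia cohort.

Thirteen per-subject features in five modality groups:

* demographic — age (years), gender (Male=1, Female=2)
* imaging — mean cortical thickness of temporal + precuneus regions
  (``mct``, mm) and total hippocampal volume (``thv``, cm^3)
* cognitive — composite memory / executive function / language scores
  (``mem``, ``exf``, ``lan``; unitless z-like composites)
* neuropsychological — Geriatric Depression Scale (``gds``), Montreal
  Cognitive Assessment (``moca``), Mini-Mental State Examination
  (``mmse``); all in points
* biomarker — amyloid-beta and tau positivity (Positive=+1,
  Negative=-1) and the Polygenic Hazard Score (``phs``)

The diagnostic label takes values NC (normal cognition), MCI (mild
cognitive impairment) and AD (Alzheimer's disease).
"""

from __future__ import annotations

CLASSES: tuple[str, ...] = ("NC", "MCI", "AD")

#: Column order of the canonical CSV layout (after ``id`` and ``label``).
FEATURES: tuple[str, ...] = (
    "age", "gender", "mct", "thv", "mem", "exf", "lan",
    "gds", "moca", "mmse", "abeta", "tau", "phs",
)

GROUPS: dict[str, tuple[str, ...]] = {
    "demographic": ("age", "gender"),
    "imaging": ("mct", "thv"),
    "cognitive": ("mem", "exf", "lan"),
    "neuropsychological": ("gds", "moca", "mmse"),
    "biomarker": ("abeta", "tau", "phs"),
}

#: Short aliases used in modality-ablation tables: D, MRI, CT, NT, BM.
GROUP_ALIASES: dict[str, str] = {
    "D": "demographic",
    "MRI": "imaging",
    "CT": "cognitive",
    "NT": "neuropsychological",
    "BM": "biomarker",
}

CATEGORICAL_FEATURES: tuple[str, ...] = ("gender", "abeta", "tau")
CONTINUOUS_FEATURES: tuple[str, ...] = tuple(
    f for f in FEATURES if f not in CATEGORICAL_FEATURES
)

#: Measures used to build the population graph.
SIMILARITY_FEATURES: tuple[str, ...] = ("mem", "exf", "lan")

#: Encoded category values. Gender: Male=1, Female=2. Biomarkers: +1/-1.
CATEGORY_CODES: dict[str, tuple[float, float]] = {
    "gender": (2.0, 1.0),   # (first, second) = (F, M)
    "abeta": (1.0, -1.0),   # (positive, negative)
    "tau": (1.0, -1.0),
}

#: Hard instrument bounds (lo, hi); None = unbounded on that side.
BOUNDS: dict[str, tuple[float | None, float | None]] = {
    "age": (40.0, 100.0),
    "mct": (0.0, None),
    "thv": (0.0, None),
    "mem": (None, None),
    "exf": (None, None),
    "lan": (None, None),
    "gds": (0.0, 30.0),
    "moca": (0.0, 30.0),
    "mmse": (0.0, 30.0),
    "phs": (None, None),
}

#: Features for which a *lower* value is clinically worse; used to
#: orient the qualitative severity bins in text explanations.
LOWER_IS_WORSE: tuple[str, ...] = ("mmse", "moca", "mem", "exf", "lan", "mct", "thv")

CSV_HEADER: tuple[str, ...] = ("id", "label") + FEATURES


def group_of(feature: str) -> str:
    """Return the modality group a feature belongs to."""
    for g, members in GROUPS.items():
        if feature in members:
            return g
    raise KeyError(f"unknown feature: {feature!r}")


def resolve_groups(spec: str) -> tuple[str, ...]:
    """Resolve a subset spec like ``"D+CT+NT"`` to canonical group names."""
    names = []
    for token in spec.split("+"):
        token = token.strip()
        key = GROUP_ALIASES.get(token.upper(), token.lower())
        if key not in GROUPS:
            raise KeyError(f"unknown modality group: {token!r}")
        names.append(key)
    return tuple(names)
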