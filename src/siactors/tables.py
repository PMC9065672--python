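"""Printed case-study constants: actor roster, ranks, priors and baselines.

The case study is a 220 km^2 Dutch peri-urban area dominated by dairy
(284 farms) and fruit (71 farms) production.  Seven actors (or actor
aggregates) steer farmers' uptake of three sustainable-intensification
measures:

* ``FoA1_3`` — establishment/maintenance of small landscape elements,
* ``FoA2``  — farm-level efficiency measures,
* ``FoA4``  — direct sales.

Several printed categorical rows do not sum to exactly 100% (rounding and
typos in the source tables); :func:`normalize` rescales them on load and
warns when the deviation is larger than rounding noise.
"""

from __future__ import annotations

import warnings

import numpy as np

SECTORS = ("dairy", "fruit")
MEASURES = ("FoA1_3", "FoA2", "FoA4")

ATTITUDE_STATES = ("supportive", "neutral", "unsupportive")

#: Actors present as nodes in the belief networks.  "Network" is the farmers'
#: informal peer network (and carries the Farmers entries of the importance
#: ranking); "NGOs" carries the farmer-organizations entries.
ACTORS = ("Retail", "NGOs", "Network", "Labels", "Province", "NL&EU", "Consumers")

ACTOR_STATES = {name: ATTITUDE_STATES for name in ACTORS}
ACTOR_STATES["Labels"] = ("supportive", "neutral")  # no unsupportive state


def normalize(values, what: str = "distribution") -> tuple[float, ...]:
    """Rescale a categorical distribution to sum to 1, warning on misprints."""
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any():
        raise ValueError(f"{what}: negative probability")
    total = arr.sum()
    if total <= 0:
        raise ValueError(f"{what}: cannot normalize an all-zero distribution")
    if abs(total - 1.0) > 0.005:
        warnings.warn(
            f"{what}: entries sum to {total:.3f}; renormalizing", stacklevel=2
        )
    return tuple((arr / total).tolist())


#: Baseline actor attitude priors (supportive, neutral[, unsupportive]).
ACTOR_PRIORS = {
    "dairy": {
        "Retail": (1 / 3, 1 / 3, 1 / 3),
        "NGOs": (1 / 3, 1 / 3, 1 / 3),
        "Network": (1 / 3, 1 / 3, 1 / 3),
        "Labels": (0.50, 0.50),
        "Province": (1 / 3, 1 / 3, 1 / 3),
        "NL&EU": (1 / 3, 1 / 3, 1 / 3),
        "Consumers": (0.19, 0.28, 0.53),
    },
    "fruit": {
        "Retail": (1 / 3, 1 / 3, 1 / 3),
        "NGOs": (1 / 3, 1 / 3, 1 / 3),
        "Network": (1 / 3, 1 / 3, 1 / 3),
        "Labels": (0.50, 0.50),
        "Province": (1 / 3, 1 / 3, 1 / 3),
        "NL&EU": (1 / 3, 1 / 3, 1 / 3),
        "Consumers": (0.28, 0.37, 0.38),  # printed row sums to 103%
    },
}

#: Farm / farmer characteristic priors per sector.
CHARACTERISTIC_PRIORS = {
    "dairy": {
        "intrinsic_attitude": (0.45, 0.27, 0.28),  # supportive / neutral / unsupportive
        "age": (0.21, 0.53, 0.26),                 # young / medium / old
        "innovative": (0.10, 0.75, 0.15),          # yes / neutral / no
        "successor": (0.29, 0.71),                 # yes / no
        "size": (0.26, 0.58, 0.17),                # small / medium / large (sums 101%)
        "location": (0.24, 0.42, 0.34),            # close / medium / remote
    },
    "fruit": {
        "intrinsic_attitude": (0.42, 0.29, 0.29),
        "age": (0.29, 0.37, 0.34),
        "innovative": (0.10, 0.80, 0.10),
        "successor": (0.07, 0.93),
        "size": (0.36, 0.37, 0.27),
        "location": (0.30, 0.57, 0.34),            # printed row sums to 121%
    },
}

CHARACTERISTIC_STATES = {
    "intrinsic_attitude": ("supportive", "neutral", "unsupportive"),
    "age": ("young", "medium", "old"),
    "innovative": ("yes", "neutral", "no"),
    "successor": ("yes", "no"),
    "size": ("small", "medium", "large"),
    "location": ("close", "medium", "remote"),
}

#: Actor groups used in the sensitivity suites.  Every actor is local or
#: external and formal or informal; market/government membership is partial.
ACTOR_GROUPS = {
    "Retail": {"external", "market", "formal"},
    "NGOs": {"external", "informal"},          # farmer organizations
    "Network": {"local", "informal"},          # farmers / peer network
    "Labels": {"external", "market", "informal"},
    "Province": {"local", "government", "formal"},
    "NL&EU": {"external", "government", "formal"},
    "Consumers": {"local", "market", "informal"},
}

#: Importance ranking of actors per measure (most important first).  The
#: printed ranking contains ties; they are broken by table row order, giving
#: the strict orderings below.  Farmers -> Network, farmer orgs -> NGOs.
RANKED_ACTORS = {
    "FoA1_3": ("Province", "NL&EU", "Retail", "Labels", "Network", "Consumers"),
    "FoA2": ("NL&EU", "Retail", "Labels", "Network", "NGOs"),
    "FoA4": ("Network", "Consumers", "Retail", "Province", "Labels"),
}

#: Baseline advice-positive probability per sector and measure.
ADVICE_TARGETS = {
    "dairy": {"FoA1_3": 0.52, "FoA2": 0.57, "FoA4": 0.40},
    "fruit": {"FoA1_3": 0.52, "FoA2": 0.56, "FoA4": 0.41},
}

#: Baseline intention-positive probability per sector and measure.
INTENTION_TARGETS = {
    "dairy": {"FoA1_3": 0.52, "FoA2": 0.49, "FoA4": 0.29},
    "fruit": {"FoA1_3": 0.51, "FoA2": 0.45, "FoA4": 0.30},
}

#: Baseline uptake-yes probability per sector and measure.
UPTAKE_TARGETS = {
    "dairy": {"FoA1_3": 0.36, "FoA2": 0.53, "FoA4": 0.20},
    "fruit": {"FoA1_3": 0.35, "FoA2": 0.40, "FoA4": 0.22},
}

#: Baseline subsidies distribution (high / medium / low); printed row sums 97%.
SUBSIDY_TARGETS = {
    "dairy": (0.64, 0.16, 0.17),
    "fruit": (0.64, 0.16, 0.17),
}

#: Baseline regulations distributions (high / medium / none) are printed per
#: measure; the model carries one Regulations node, targeted at their mean.
REGULATION_TARGETS_PRINTED = {
    "dairy": {"FoA2": (0.62, 0.28, 0.11), "FoA1_3": (0.61, 0.28, 0.11)},
    "fruit": {"FoA2": (0.60, 0.29, 0.11), "FoA1_3": (0.61, 0.28, 0.10)},
}


def regulation_target(sector: str) -> tuple[float, ...]:
    rows = [normalize(r, "regulations") for r in REGULATION_TARGETS_PRINTED[sector].values()]
    return tuple(np.mean(rows, axis=0).tolist())


#: Observed adoption shares quoted alongside the scenario table; available as
#: an alternative percent-change baseline.
OBSERVED_ADOPTION = {
    "dairy": {"FoA1_3": 0.29, "FoA2": 0.45, "FoA4": 0.11},
    "fruit": {"FoA1_3": 0.14, "FoA2": 0.33, "FoA4": 0.09},
}

N_DAIRY = 284
N_FRUIT = 71
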