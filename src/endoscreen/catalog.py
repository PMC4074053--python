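"""Canonical catalog of the 27 per-cell features.

Naming follows the screen's convention: the ``F`` prefix marks the
fluid-phase (dextran, CLIC/GEEC pathway) channel, ``T`` the transferrin
(clathrin-dependent pathway) channel.  ``int`` features are mean
intensities after top-hat background subtraction at decreasing disk
radii, ``mph`` features are endosome morphology, ``num`` endosome
counts, ``clc`` two-way colocalization fractions, ``Okt`` the surface
level of the transferrin receptor, and ``Rto`` the internal-to-surface
transferrin ratios.  The remaining features describe nuclear and cell
geometry.
"""

from __future__ import annotations

FLUID_FEATURES = (
    "Fint1", "Fint2", "Fint3", "Fint4",
    "Fmph1", "Fmph2", "Fmph3",
    "Fnum", "Fclc",
)

TF_FEATURES = (
    "Tint1", "Tint2", "Tint3", "Tint4",
    "Tmph1", "Tmph2", "Tmph3",
    "Tnum", "Okt",
    "Rto1", "Rto2", "Rto3",
    "Tclc",
)

NUCLEAR_FEATURES = ("NucSize", "NucCirc", "NucFluct", "NucDist")

CELLSIZE_FEATURES = ("CellSize",)

FEATURES = FLUID_FEATURES + TF_FEATURES + NUCLEAR_FEATURES + CELLSIZE_FEATURES

#: Features whose values are fractions bounded in [0, 1].
FRACTION_FEATURES = frozenset(
    {"Fint4", "Tint4", "Fmph2", "Tmph2", "Fmph3", "Tmph3",
     "Fclc", "Tclc", "NucCirc"}
)

#: Features that are non-negative counts (per-cell averages may be real).
COUNT_FEATURES = frozenset({"Fnum", "Tnum"})

N_FEATURES = len(FEATURES)

assert N_FEATURES == 27

FEATURE_INDEX = {name: i for i, name in enumerate(FEATURES)}


def feature_pathway(feature: str) -> str:
    """Return the pathway group a feature reports on.

    One of ``"fluid"``, ``"tf"``, ``"nuclear"``, ``"cellsize"``.
    """
    if feature in FLUID_FEATURES:
        return "fluid"
    if feature in TF_FEATURES:
        return "tf"
    if feature in NUCLEAR_FEATURES:
        return "nuclear"
    if feature in CELLSIZE_FEATURES:
        return "cellsize"
    raise KeyError(f"unknown feature {feature!r}")
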