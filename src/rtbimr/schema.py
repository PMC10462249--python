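"""Canonical feature-table schema for the 20-mouse rTBI/Sham cohort.

The study quantifies 44 variables per mouse: elevated-plus-maze (EPM)
behavior, hyperpolarized (HP) 13C imaging readouts, enzyme activities
(PDH, LDH), monocarboxylate-transporter expression (MCT1, MCT4),
structural MRI (normalized T2, regional volumes), T1 relaxation times
and susceptibility-weighted imaging (SWI) intensities, each resolved by
brain region (Pfc = prefrontal cortex, Ctx = cortex, Hp = hippocampus,
Thal = thalamus, Subctx = subcortex).
"""

from __future__ import annotations

GROUPS = ("Sham", "rTBI")

EPM_VARIABLES = (
    "EPM frequency extreme",
    "EPM duration extreme",
    "EPM frequency openandcenter",
    "EPM duration openandcenter",
    "EPM totaldistance centerpoint",
    "EPM averagevelocity centerpoint",
)

HP_VARIABLES = (
    "HP 13C Urea Ctx",
    "HP 13C Lac/Pyr Ctx",
    "HP 13C Urea Subctx",
    "HP 13C Lac/Pyr Subctx",
)

PDH_VARIABLES = ("PDH Pfc", "PDH Ctx", "PDH Hp", "PDH Thal")

NT2_VARIABLES = ("nT2 Ctx", "nT2 Hp", "nT2 Pfc", "nT2 Subctx")

VOLUME_VARIABLES = (
    "Volume Ctx",
    "Volume Hp",
    "Volume Pfc",
    "Volume Subctx",
    "Volume Ventricle",
    "Volume Brain",
)

T1_VARIABLES = ("T1 Ctx", "T1 Hp", "T1 Pfc", "T1 Subctx")

MCT1_VARIABLES = ("MCT1 Thal", "MCT1 Hp", "MCT1 Ctx", "MCT1 Pfc")

MCT4_VARIABLES = ("MCT4 Thal", "MCT4 Hp", "MCT4 Ctx", "MCT4 Pfc")

LDH_VARIABLES = ("LDH Thal", "LDH Hp", "LDH Ctx", "LDH Pfc")

SWI_VARIABLES = ("SWI Ctx", "SWI Hp", "SWI Pfc", "SWI Subctx")

#: All 44 measured variables, in table order.
FEATURE_VARIABLES: tuple[str, ...] = (
    EPM_VARIABLES
    + HP_VARIABLES
    + PDH_VARIABLES
    + NT2_VARIABLES
    + VOLUME_VARIABLES
    + T1_VARIABLES
    + MCT1_VARIABLES
    + MCT4_VARIABLES
    + LDH_VARIABLES
    + SWI_VARIABLES
)

N_FEATURES = len(FEATURE_VARIABLES)

#: Region labels used on the CSI grid.
CSI_REGIONS = ("cortex", "subcortex", "surrounding", "background")

#: Brain regions carrying ROI statistics.
BRAIN_REGIONS = (
    "prefrontal cortex",
    "cortex",
    "hippocampus",
    "thalamus",
    "subcortex",
    "ventricles",
    "brain",
)


def validate_variables(names) -> None:
    """Raise ``KeyError`` if any name is not in the canonical schema."""
    unknown = [n for n in names if n not in FEATURE_VARIABLES]
    if unknown:
        raise KeyError(f"unknown feature variables: {unknown}")
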