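"""Somatic copy-state classification from (allele proportion, normalized CN).

Each candidate state has a closed-form forward prediction as a function of
the clonal fraction ``f`` (share of cells carrying the event, mixed with
diploid heterozygous cells).  Classification fits ``f`` per model by
least squares on the (proportion, normalized copy number) plane and keeps
the model with the smallest Euclidean residual; near-ties are flagged
ambiguous, and degenerate coincidences resolve to the simplest state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .ai import SampleMeasurement
from .droplet import ChannelConcentration
from .errors import ValidationError

MODEL_DIPLOID = "diploid"
MODEL_HOM_DEL = "hom_del"
MODEL_HEMI_DEL_PROT_LOST = "hemi_del_prot_lost"
MODEL_HEMI_DEL_RISK_LOST = "hemi_del_risk_lost"
MODEL_CNLOH_RISK = "cnloh_risk"
MODEL_CNLOH_PROT = "cnloh_prot"
MODEL_GAIN_RISK = "gain_risk"
MODEL_GAIN_PROT = "gain_prot"
MODEL_TETRAPLOID_RISK = "tetraploid_3to1_risk"
MODEL_TETRAPLOID_PROT = "tetraploid_3to1_prot"

MODELS = (
    MODEL_DIPLOID,
    MODEL_HOM_DEL,
    MODEL_HEMI_DEL_PROT_LOST,
    MODEL_HEMI_DEL_RISK_LOST,
    MODEL_CNLOH_RISK,
    MODEL_CNLOH_PROT,
    MODEL_GAIN_RISK,
    MODEL_GAIN_PROT,
    MODEL_TETRAPLOID_RISK,
    MODEL_TETRAPLOID_PROT,
)

# Fewest somatic events first; used only to break residual ties.
_COMPLEXITY = {
    MODEL_DIPLOID: 0,
    MODEL_HEMI_DEL_PROT_LOST: 1,
    MODEL_HEMI_DEL_RISK_LOST: 1,
    MODEL_GAIN_RISK: 1,
    MODEL_GAIN_PROT: 1,
    MODEL_HOM_DEL: 2,
    MODEL_CNLOH_RISK: 2,
    MODEL_CNLOH_PROT: 2,
    MODEL_TETRAPLOID_RISK: 3,
    MODEL_TETRAPLOID_PROT: 3,
}

MIRROR = {
    MODEL_DIPLOID: MODEL_DIPLOID,
    MODEL_HOM_DEL: MODEL_HOM_DEL,
    MODEL_HEMI_DEL_PROT_LOST: MODEL_HEMI_DEL_RISK_LOST,
    MODEL_HEMI_DEL_RISK_LOST: MODEL_HEMI_DEL_PROT_LOST,
    MODEL_CNLOH_RISK: MODEL_CNLOH_PROT,
    MODEL_CNLOH_PROT: MODEL_CNLOH_RISK,
    MODEL_GAIN_RISK: MODEL_GAIN_PROT,
    MODEL_GAIN_PROT: MODEL_GAIN_RISK,
    MODEL_TETRAPLOID_RISK: MODEL_TETRAPLOID_PROT,
    MODEL_TETRAPLOID_PROT: MODEL_TETRAPLOID_RISK,
}

# Models fitted directly; "*_prot" variants are evaluated by mirroring the
# observation, which makes risk/protective symmetry exact by construction.
_CANONICAL = (
    MODEL_DIPLOID,
    MODEL_HOM_DEL,
    MODEL_HEMI_DEL_PROT_LOST,
    MODEL_CNLOH_RISK,
    MODEL_GAIN_RISK,
    MODEL_TETRAPLOID_RISK,
)

DEFAULT_AMBIGUITY_MARGIN = 0.02
_F_GRID = np.linspace(0.0, 1.0, 1001)


@dataclass(frozen=True)
class CopyNumberEstimate:
    sample_id: str
    normalized_cn: float
    control_conc: float

    def __post_init__(self) -> None:
        if self.normalized_cn < 0:
            raise ValidationError("normalized_cn must be non-negative")
        if not self.control_conc > 0:
            raise ValidationError("control concentration must be positive")


@dataclass(frozen=True)
class AlterationCall:
    sample_id: str
    model: str
    clonal_fraction: float
    residual: float
    ambiguous: bool


def normalized_copy_number(
    m: SampleMeasurement, control: ChannelConcentration | float
) -> CopyNumberEstimate:
    """Total SNP-locus concentration over the genomic-control concentration.

    1.0 means diploid relative to the unaltered control region.
    """
    conc = (
        control.concentration_copies_per_ul
        if isinstance(control, ChannelConcentration)
        else float(control)
    )
    if conc <= 0:
        raise ValidationError(
            "genomic control concentration is zero; check the control assay wells"
        )
    return CopyNumberEstimate(
        sample_id=m.sample_id,
        normalized_cn=(m.mean_conc_risk + m.mean_conc_prot) / conc,
        control_conc=conc,
    )


def forward_state(model: str, clonal_fraction: float | np.ndarray):
    """Expected (risk proportion, normalized CN) for a state at fraction f.

    A fraction ``f`` of cells carry the event; the remainder stay diploid
    heterozygous (1 risk + 1 protective copy).  At f = 0 every model
    coincides with the diploid point (0.5, 1.0).
    """
    f = np.asarray(clonal_fraction, dtype=float)
    if np.any(f < 0) or np.any(f > 1):
        raise ValidationError("clonal_fraction must lie in [0, 1]")
    one = np.ones_like(f)
    if model == MODEL_DIPLOID:
        prop, cn = 0.5 * one, one
    elif model == MODEL_HOM_DEL:
        prop, cn = 0.5 * one, 1.0 - f
    elif model == MODEL_HEMI_DEL_PROT_LOST:
        prop, cn = 1.0 / (2.0 - f), 1.0 - f / 2.0
    elif model == MODEL_HEMI_DEL_RISK_LOST:
        prop, cn = 1.0 - 1.0 / (2.0 - f), 1.0 - f / 2.0
    elif model == MODEL_CNLOH_RISK:
        prop, cn = (1.0 + f) / 2.0, one
    elif model == MODEL_CNLOH_PROT:
        prop, cn = 1.0 - (1.0 + f) / 2.0, one
    elif model == MODEL_GAIN_RISK:
        prop, cn = (1.0 + f) / (2.0 + f), (2.0 + f) / 2.0
    elif model == MODEL_GAIN_PROT:
        prop, cn = 1.0 - (1.0 + f) / (2.0 + f), (2.0 + f) / 2.0
    elif model == MODEL_TETRAPLOID_RISK:
        prop, cn = (1.0 + 2.0 * f) / (2.0 + 2.0 * f), 1.0 + f
    elif model == MODEL_TETRAPLOID_PROT:
        prop, cn = 1.0 - (1.0 + 2.0 * f) / (2.0 + 2.0 * f), 1.0 + f
    else:
        raise ValidationError(f"unknown copy-state model {model!r}")
    if np.ndim(clonal_fraction) == 0:
        return float(prop), float(cn)
    return prop, cn


def _fit_model(model: str, p: float, c: float) -> tuple[float, float]:
    """Best clonal fraction and squared residual for one model."""
    if model == MODEL_DIPLOID:
        return 0.0, (0.5 - p) ** 2 + (1.0 - c) ** 2
    prop, cn = forward_state(model, _F_GRID)
    d2 = (prop - p) ** 2 + (cn - c) ** 2
    i = int(np.argmin(d2))
    lo = _F_GRID[max(i - 1, 0)]
    hi = _F_GRID[min(i + 1, len(_F_GRID) - 1)]
    if hi > lo:
        res = minimize_scalar(
            lambda f: (forward_state(model, float(f))[0] - p) ** 2
            + (forward_state(model, float(f))[1] - c) ** 2,
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-9},
        )
        if res.fun <= d2[i]:
            return float(np.clip(res.x, 0.0, 1.0)), float(res.fun)
    return float(_F_GRID[i]), float(d2[i])


def classify_alteration(
    proportion: float,
    cn: CopyNumberEstimate | float,
    min_residual_margin: float = DEFAULT_AMBIGUITY_MARGIN,
    *,
    sample_id: str = "",
) -> AlterationCall:
    """Fit every candidate state and return the one with minimal residual.

    Observations with proportion < 0.5 are mirrored onto the risk-majority
    side, classified, and mapped back, so risk/protective symmetry is exact.
    States whose best fits tie in residual resolve to the fewest-event
    model; a genuinely different runner-up within ``min_residual_margin``
    marks the call ambiguous.
    """
    if not 0.0 <= proportion <= 1.0:
        raise ValidationError("proportion must lie in [0, 1]")
    c = cn.normalized_cn if isinstance(cn, CopyNumberEstimate) else float(cn)
    if c < 0:
        raise ValidationError("normalized copy number must be non-negative")
    if isinstance(cn, CopyNumberEstimate) and not sample_id:
        sample_id = cn.sample_id

    mirrored = proportion < 0.5
    p = 1.0 - proportion if mirrored else proportion

    fits = []  # (residual^2, complexity, model, f)
    for model in _CANONICAL:
        f_hat, d2 = _fit_model(model, p, c)
        fits.append((d2, _COMPLEXITY[model], model, f_hat))

    best_d2 = min(d2 for d2, _, _, _ in fits)
    tied = [fit for fit in fits if fit[0] - best_d2 <= 1e-12]
    tied.sort(key=lambda fit: (fit[1], fit[2]))
    d2, _, model, f_hat = tied[0]
    residual = float(np.sqrt(d2))

    # A runner-up model predicting a genuinely different point but fitting
    # nearly as well makes the call ambiguous.  Mirror-image models fitted
    # to the reflected observation cover the opposite-allele states, which
    # can tie when the proportion sits near 0.5 (they never win outright
    # because the canonical side is at least as close).
    rivals = list(fits)
    for other in _CANONICAL:
        if MIRROR[other] == other:
            continue
        f_m, d2_m = _fit_model(other, 1.0 - p, c)
        rivals.append((d2_m, _COMPLEXITY[other], MIRROR[other], f_m))
    best_pred = forward_state(model, f_hat)
    ambiguous = False
    for other_d2, _, other_model, other_f in rivals:
        if other_model == model:
            continue
        if np.sqrt(other_d2) - residual < min_residual_margin:
            other_pred = forward_state(other_model, other_f)
            if max(
                abs(other_pred[0] - best_pred[0]), abs(other_pred[1] - best_pred[1])
            ) > 1e-9:
                ambiguous = True
                break

    if mirrored:
        model = MIRROR[model]
    return AlterationCall(
        sample_id=sample_id,
        model=model,
        clonal_fraction=f_hat,
        residual=residual,
        ambiguous=ambiguous,
    )
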