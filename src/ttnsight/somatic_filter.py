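"""Tumor-only somatic candidate filtering.

Without a matched normal, caller output mixes true somatic mutations with
germline polymorphisms.  The cascade applied here: keep only PASS /
germline_risk caller labels, drop population-database and panel-of-normals
hits, apply depth thresholds, drop intronic candidates, then adjudicate the
remaining germline_risk calls against the VAF distribution of the sample's
PASS calls with a Gaussian kernel density — a germline_risk call whose VAF
falls where the somatic density is ≈0 (below ``epsilon``) is discarded,
unless rescued by concordant deleterious SIFT and damaging PolyPhen-2
annotations.  POLE calls are pathogenic only within the exonuclease
(proofreading) domain.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Density threshold under which a germline_risk VAF is deemed outside the
#: somatic distribution.  A unit-mass Gaussian-kernel density more than ~4
#: bandwidths from every support point falls below this for typical n.
DEFAULT_EPSILON = 1e-3

#: POLE exonuclease-domain protein residues (configurable).
POLE_EXO_DOMAIN = (268, 471)

CALL_COLUMNS = [
    "sample_id",
    "gene",
    "variant_type",
    "filter_label",
    "total_depth",
    "alt_depth",
    "vaf",
    "in_population_db",
    "in_pon",
    "is_intronic",
    "sift",
    "polyphen",
    "pole_exonuclease_domain",
]


class DensityFitError(ValueError):
    """The PASS VAF set is too degenerate to support a kernel density."""


@dataclass(frozen=True)
class DensityModel:
    """Gaussian kernel density over PASS variant allele fractions.

    Bandwidth is the Silverman rule in its exact form
    ``h = (4 sigma^5 / (3 n))^(1/5)`` with ``sigma`` the ddof=1 standard
    deviation of the support points.
    """

    x: np.ndarray
    n: int
    sigma: float
    h: float

    def __call__(self, v) -> np.ndarray | float:
        """Evaluate the density f(v) = (1/(n h)) sum_i K((v - x_i)/h)."""
        v = np.asarray(v, dtype=float)
        u = (v[..., None] - self.x) / self.h
        k = np.exp(-0.5 * u * u) / math.sqrt(2.0 * math.pi)
        out = k.sum(axis=-1) / (self.n * self.h)
        return float(out) if out.ndim == 0 else out


def fit_density(pass_vafs) -> DensityModel:
    """Fit the somatic-VAF kernel density from PASS call VAFs.

    Raises :class:`DensityFitError` when fewer than two distinct VAFs are
    available (no spread to estimate a bandwidth from).
    """
    x = np.asarray(pass_vafs, dtype=float)
    n = x.size
    if n < 2:
        raise DensityFitError(f"need >= 2 PASS VAFs to fit a density, got {n}")
    sigma = float(x.std(ddof=1))
    if sigma < 1e-12:  # identical support points up to rounding
        raise DensityFitError("PASS VAFs have zero spread; bandwidth undefined")
    h = (4.0 * sigma**5 / (3.0 * n)) ** 0.2
    return DensityModel(x=x, n=n, sigma=sigma, h=h)


def primary_filter(calls: pd.DataFrame) -> pd.DataFrame:
    """Keep only calls labeled PASS or germline_risk by the caller."""
    return calls[calls["filter_label"].isin(["PASS", "germline_risk"])]


def database_filter(calls: pd.DataFrame) -> pd.DataFrame:
    """Drop calls present in the population database or the panel of normals."""
    return calls[~(calls["in_population_db"].astype(bool) | calls["in_pon"].astype(bool))]


def depth_filter(calls: pd.DataFrame) -> pd.DataFrame:
    """Drop low-evidence calls.

    A call is removed if total depth < 30, or it is an SNV with fewer than 3
    alt reads, or an indel with fewer than 5 alt reads (any single failure
    removes the call).
    """
    depth = calls["total_depth"].to_numpy()
    alt = calls["alt_depth"].to_numpy()
    if (depth < 0).any() or (alt < 0).any():
        raise ValueError("negative read depths")
    is_snv = (calls["variant_type"] == "SNV").to_numpy()
    fail = (depth < 30) | (is_snv & (alt < 3)) | (~is_snv & (alt < 5))
    return calls[~fail]


def intronic_filter(calls: pd.DataFrame) -> pd.DataFrame:
    return calls[~calls["is_intronic"].astype(bool)]


def germline_risk_rescue(
    calls: pd.DataFrame, model: DensityModel, epsilon: float = DEFAULT_EPSILON
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split germline_risk calls by the somatic density at their VAF.

    Returns ``(kept, discarded)``: germline_risk calls with density below
    ``epsilon`` are discarded as true germline; the rest are promoted to
    somatic candidates.  PASS calls pass through untouched.
    """
    gr = calls["filter_label"] == "germline_risk"
    if not gr.any():
        return calls, calls.iloc[0:0]
    dens = np.asarray(model(calls.loc[gr, "vaf"].to_numpy()))
    discard_idx = calls.index[gr][dens < epsilon]
    return calls.drop(index=discard_idx), calls.loc[discard_idx]


def annotation_rescue(discarded: pd.DataFrame) -> pd.DataFrame:
    """Rescue density-discarded calls with concordant damaging annotations.

    A call is rescued iff SIFT predicts deleterious AND PolyPhen-2 predicts
    probably or possibly damaging.
    """
    ok = (discarded["sift"] == "deleterious") & (
        discarded["polyphen"].isin(["probably_damaging", "possibly_damaging"])
    )
    return discarded[ok]


def pole_pathogenic(call) -> bool:
    """Whether a POLE call is pathogenic (within the exonuclease domain).

    ``call`` is a mapping/row with ``gene`` and ``pole_exonuclease_domain``.
    """
    if call["gene"] != "POLE":
        raise ValueError("pole_pathogenic applies only to POLE calls")
    return bool(call["pole_exonuclease_domain"])


def sample_pole_status(calls: pd.DataFrame) -> str:
    """exonuclease_mutant iff any POLE call lies in the proofreading domain."""
    pole = calls[calls["gene"] == "POLE"]
    if len(pole) and pole["pole_exonuclease_domain"].astype(bool).any():
        return "exonuclease_mutant"
    return "wildtype"


def run_filter_cascade(
    calls: pd.DataFrame, epsilon: float = DEFAULT_EPSILON
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the full tumor-only filter cascade; return (somatic, audit).

    Stage order: caller-label filter, database filter, depth filter,
    intronic drop, per-sample kernel-density adjudication of germline_risk
    calls, annotation rescue of density-discarded calls.  ``audit`` maps
    stage name to calls removed at that stage (``rescued`` counts calls
    added back).  When a sample's PASS VAFs cannot support a density fit its
    germline_risk calls are retained unchanged (logged).
    """
    audit: dict[str, int] = {}
    stages = [
        ("primary", primary_filter),
        ("database", database_filter),
        ("depth", depth_filter),
        ("intronic", intronic_filter),
    ]
    current = calls
    for name, fn in stages:
        nxt = fn(current)
        audit[name] = len(current) - len(nxt)
        current = nxt

    kept_parts, rescued_parts = [], []
    n_discarded = n_rescued = 0
    for sample_id, grp in current.groupby("sample_id", sort=True):
        pass_vafs = grp.loc[grp["filter_label"] == "PASS", "vaf"].to_numpy()
        try:
            model = fit_density(pass_vafs)
        except DensityFitError as exc:
            log.warning("sample %s: %s; retaining germline_risk calls unchanged", sample_id, exc)
            kept_parts.append(grp)
            continue
        kept, discarded = germline_risk_rescue(grp, model, epsilon)
        rescued = annotation_rescue(discarded)
        n_discarded += len(discarded)
        n_rescued += len(rescued)
        kept_parts.append(kept)
        rescued_parts.append(rescued)
    audit["density"] = n_discarded
    audit["rescued"] = n_rescued

    parts = kept_parts + rescued_parts
    somatic = pd.concat(parts).sort_index() if parts else current.iloc[0:0]
    return somatic, audit
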