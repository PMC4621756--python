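"""Synthetic spectral-count panels with known sparse ground truth.

The generator emulates the statistical structure of a label-free
glycoproteomics study of breast-cancer cell lines: a features x cell-lines
matrix of spectral counts acquired on two instruments with different
scale/dispersion, a handful of "household" proteins whose abundance barely
varies across cell lines (the normalization anchors), and drug sensitivities
(-log10 GI50) generated by a sparse linear model on the log10 counts.

Counts are drawn as log-normal per-protein means combined with
negative-binomial per-cell sampling, which reproduces the overdispersion
typical of spectral counting.  Household proteins use a high Poisson mean so
their across-cell-line coefficient of variation stays below ~0.1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .matrix import validate_counts


@dataclass(frozen=True)
class InstrumentProfile:
    """Affine distortion + count dispersion of one mass spectrometer.

    scale/offset distort the counts (x -> scale*x + offset, clipped at 0 and
    rounded); dispersion is the negative-binomial size parameter (smaller =
    more overdispersed; variance = m + m^2/dispersion).
    """

    scale: float = 1.0
    offset: float = 0.0
    dispersion: float = 2.0
    label: str = "instrument"

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError("scale must be positive")
        if not self.dispersion > 0:
            raise ValueError("dispersion must be positive")


UNIT_PROFILE = InstrumentProfile(label="unit")


@dataclass
class SyntheticTruth:
    """Ground truth behind one simulated drug response."""

    true_predictor_ids: list[str]
    true_beta: dict[str, float]
    intercept: float
    noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        nonzero = sorted(k for k, v in self.true_beta.items() if v != 0.0)
        if nonzero != sorted(self.true_predictor_ids):
            raise ValueError("true_predictor_ids must be the nonzero keys of true_beta")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


# Mean spectral count of household anchors; Poisson CV ~ 1/sqrt(mean) ~ 0.07.
_HOUSEHOLD_LOG_MEAN = np.log(200.0)
_HOUSEHOLD_LOG_SD = 0.3
# Log-normal spread of ordinary protein means (median ~8 counts).
_PROTEIN_LOG_MEAN = np.log(8.0)
_PROTEIN_LOG_SD = 1.2


def generate_spectral_counts(
    n_cell_lines: int,
    n_proteins: int,
    n_household: int,
    profile: InstrumentProfile = UNIT_PROFILE,
    seed: int = 0,
    feature_prefix: str = "P",
    cell_line_prefix: str = "CL",
) -> pd.DataFrame:
    """Simulate a features x cell-lines spectral-count matrix.

    The first ``n_household`` rows are household proteins: one constant mean
    per protein shared by all cell lines, Poisson-sampled so their CV across
    cell lines is small.  Remaining proteins draw a per-(protein, cell line)
    mean from a log-normal and counts from a negative binomial with the
    profile's dispersion.  Finally the profile's affine distortion is
    applied, clipped at zero and rounded to integer counts.
    """
    if n_cell_lines <= 0 or n_proteins <= 0:
        raise ValueError("dimensions must be positive")
    if n_household < 0 or n_household > n_proteins:
        raise ValueError("n_household must be in [0, n_proteins]")
    if not isinstance(profile, InstrumentProfile):
        raise TypeError("profile must be an InstrumentProfile")

    rng = np.random.default_rng(derive_seed(seed, "counts"))
    counts = np.zeros((n_proteins, n_cell_lines))

    if n_household:
        hh_means = np.exp(rng.normal(_HOUSEHOLD_LOG_MEAN, _HOUSEHOLD_LOG_SD, n_household))
        counts[:n_household] = rng.poisson(
            np.repeat(hh_means[:, None], n_cell_lines, axis=1)
        )

    n_rest = n_proteins - n_household
    if n_rest:
        # one log-normal mean per protein; per-cell counts NB-overdispersed
        protein_means = np.exp(rng.normal(_PROTEIN_LOG_MEAN, _PROTEIN_LOG_SD, n_rest))
        r = profile.dispersion
        p = r / (r + np.repeat(protein_means[:, None], n_cell_lines, axis=1))
        counts[n_household:] = rng.negative_binomial(r, p)

    distorted = np.rint(np.clip(profile.scale * counts + profile.offset, 0.0, None))

    features = [f"{feature_prefix}{i:04d}" for i in range(n_proteins)]
    cells = [f"{cell_line_prefix}{j:02d}" for j in range(n_cell_lines)]
    return validate_counts(
        pd.DataFrame(distorted.astype(np.int64), index=features, columns=cells)
    )


def distort_counts(counts: pd.DataFrame, profile: InstrumentProfile) -> pd.DataFrame:
    """Apply an instrument's affine distortion to an existing count matrix."""
    distorted = np.rint(
        np.clip(profile.scale * counts.to_numpy(dtype=float) + profile.offset, 0.0, None)
    )
    return pd.DataFrame(distorted.astype(np.int64), index=counts.index, columns=counts.columns)


def resample_counts(counts: pd.DataFrame, dispersion: float, seed: int) -> pd.DataFrame:
    """Technical-replicate resampling: NB draws around the observed counts.

    Emulates re-acquiring the same samples; means are the observed counts
    (+0.5 to avoid degenerate zero means), dispersion controls run-to-run
    noise.
    """
    rng = np.random.default_rng(derive_seed(seed, "resample"))
    m = counts.to_numpy(dtype=float) + 0.5
    p = dispersion / (dispersion + m)
    new = rng.negative_binomial(dispersion, p)
    return pd.DataFrame(new.astype(np.int64), index=counts.index, columns=counts.columns)


def generate_drug_response(
    X: pd.DataFrame,
    k_true: int,
    beta_magnitude: float | None = None,
    noise_sd: float = 0.4,
    seed: int = 0,
    drug_id: str = "drug",
    target_r2: float | None = None,
) -> tuple[pd.Series, SyntheticTruth]:
    """Simulate one drug's sensitivities from a log-expression matrix.

    ``X`` is cell lines x features (log10 scale).  Internally the columns
    are standardized (ddof=0) and the response is

        y = intercept + X_std @ beta + Normal(0, noise_sd^2)

    with exactly ``k_true`` nonzero coefficients of magnitude
    ``beta_magnitude`` (default 1/sqrt(k_true), giving Var(X beta) ~ 1 so the
    responses span roughly four log10 units across cell lines) at positions
    chosen uniformly at random, each with a random sign.

    If ``target_r2`` is given, the common coefficient magnitude is instead
    calibrated on the realized design so that
    Var(X beta) / (Var(X beta) + noise_sd^2) equals it exactly — the signal
    fraction is then a controlled condition rather than a byproduct of the
    sampled predictor correlations.
    """
    if k_true < 0 or k_true > X.shape[1]:
        raise ValueError("k_true must be in [0, number of features]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if X.isna().any().any():
        raise ValueError("X must have no missing values")
    if beta_magnitude is None:
        beta_magnitude = 1.0 / np.sqrt(k_true) if k_true else 0.0

    rng = np.random.default_rng(derive_seed(seed, "response"))
    values = X.to_numpy(dtype=float)
    mu = values.mean(axis=0)
    sd = values.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Xs = (values - mu) / sd_safe

    # only features with variation can carry signal
    eligible = np.flatnonzero(sd > 0)
    if k_true > eligible.size:
        raise ValueError("not enough varying features for k_true")
    chosen = rng.choice(eligible, size=k_true, replace=False) if k_true else np.array([], int)
    signs = rng.choice([-1.0, 1.0], size=k_true)

    if target_r2 is not None:
        if not (0.0 < target_r2 < 1.0):
            raise ValueError("target_r2 must be in (0, 1)")
        if k_true == 0 or noise_sd == 0:
            raise ValueError("target_r2 requires k_true > 0 and noise_sd > 0")
        pattern_var = float(np.var(Xs[:, chosen] @ signs))
        beta_magnitude = noise_sd * np.sqrt(target_r2 / (1.0 - target_r2) / pattern_var)

    beta = np.zeros(X.shape[1])
    beta[chosen] = signs * beta_magnitude
    intercept = 6.0  # plausible -log10 GI50 center (micromolar-to-nanomolar range)
    noise = rng.normal(0.0, noise_sd, X.shape[0]) if noise_sd > 0 else np.zeros(X.shape[0])
    y = intercept + Xs @ beta + noise

    ids = [str(X.columns[j]) for j in sorted(chosen)]
    truth = SyntheticTruth(
        true_predictor_ids=ids,
        true_beta={str(X.columns[j]): float(beta[j]) for j in sorted(chosen)},
        intercept=intercept,
        noise_sd=float(noise_sd),
        seed=int(seed),
    )
    return pd.Series(y, index=X.index, name=drug_id), truth


@dataclass
class StudyData:
    """One simulated two-instrument study with responses and ground truth."""

    reference_counts: pd.DataFrame       # LTQ-like instrument, shared cell lines
    target_counts: pd.DataFrame          # QE-like instrument, shared + extra lines
    target_only_cell_lines: list[str]
    true_counts: pd.DataFrame            # undistorted counts, all cell lines
    responses: pd.DataFrame              # cell lines x drugs
    truths: dict[str, SyntheticTruth] = field(default_factory=dict)


def simulate_study(
    n_cell_lines: int = 22,
    n_proteins: int = 185,
    n_household: int = 7,
    n_target_only: int = 4,
    n_drugs: int = 10,
    k_true: int = 3,
    noise_sd: float = 0.4,
    target_profile: InstrumentProfile = InstrumentProfile(scale=2.5, offset=1.0, label="QE"),
    seed: int = 0,
) -> StudyData:
    """Simulate the full study layout.

    A true count matrix over all cell lines is generated once; the reference
    instrument observes all but the last ``n_target_only`` cell lines
    undistorted, while the target instrument observes every cell line through
    its affine distortion.  Drug responses come from the true log counts, so
    normalization quality is measurable downstream.
    """
    if n_target_only >= n_cell_lines:
        raise ValueError("n_target_only must be smaller than n_cell_lines")
    true_counts = generate_spectral_counts(
        n_cell_lines, n_proteins, n_household, UNIT_PROFILE, seed=derive_seed(seed, "true")
    )
    cells = list(true_counts.columns)
    target_only = cells[n_cell_lines - n_target_only :] if n_target_only else []
    reference = true_counts[cells[: n_cell_lines - n_target_only]].copy()
    target = distort_counts(true_counts, target_profile)

    log_expr = np.log10(true_counts.to_numpy(dtype=float) + 1.0).T
    X = pd.DataFrame(log_expr, index=cells, columns=true_counts.index)

    responses = {}
    truths = {}
    for d in range(n_drugs):
        drug = f"drug{d:02d}"
        y, truth = generate_drug_response(
            X, k_true=k_true, noise_sd=noise_sd, seed=derive_seed(seed, "drug", d), drug_id=drug
        )
        responses[drug] = y
        truths[drug] = truth

    return StudyData(
        reference_counts=reference,
        target_counts=target,
        target_only_cell_lines=list(target_only),
        true_counts=true_counts,
        responses=pd.DataFrame(responses),
        truths=truths,
    )
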