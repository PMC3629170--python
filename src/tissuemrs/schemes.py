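"""Labeling schemes for low-tumor-content biopsies, and report generation.

Biopsies with very low tumor cell content (TC) sit between the tumor
and non-involved classes, and the choice of how to label them changes
what the classifier learns.  Four schemes are provided:

``tumor_ge5``
    Tumor iff TC >= 5%; samples below 5% (including 1-4%) count as
    non-involved.  All samples train and test.
``tumor_gt0``
    Tumor iff TC > 0%; only 0% samples are non-involved.  All samples
    train and test.
``tumor_gt0_excl_lt5``
    As ``tumor_gt0`` but samples with 0% < TC < 5% are excluded from
    model training and scored as tumor when their patient is held out.
``tumor_gt0_excl_le5``
    As above with the exclusion widened to 0% < TC <= 5%.

On a cohort with the reference stratum structure (65 at 0%, 5 at 1-4%,
32 at 5%, 226 above 5%) the two exclusion schemes remove exactly 5 and
5+32 = 37 samples from training.

A separate entry point restricts the spectra to the choline-containing
metabolite window (3.252-3.196 ppm: GPC, PCho, free choline) so the
same pipeline can quantify how much of the discrimination that region
alone carries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chemometrics import PLSModel, PCAResult, vip_scores
from .io import RunConfig, SpectrumSet, join, validate_metadata
from .synthetic import MetabolitePeak, default_peak_library
from .validation import DCVConfig, DCVResult, double_cv, permutation_test

CHOLINE_WINDOW = (3.252, 3.196)  # (upper, lower) ppm


@dataclass(frozen=True)
class Scheme:
    """Label map plus train/test inclusion rules keyed on tumor content (%).

    ``tumor_min_tc``: smallest TC counted as tumor (inclusive bound used
    with ``tumor_strict``: if strict, tumor iff TC > tumor_min_tc,
    otherwise TC >= tumor_min_tc).  ``exclusion``: open/closed TC
    interval removed from training, or None; excluded samples are
    labeled ``excluded_test_label`` when scored.
    """

    name: str
    tumor_min_tc: float
    tumor_strict: bool  # True: tumor iff TC > tumor_min_tc; False: >=
    exclusion: tuple[float, float, bool] | None = None  # (low, high, high_inclusive)
    excluded_test_label: int = 1

    def labels(self, tc: np.ndarray) -> np.ndarray:
        if self.tumor_strict:
            return (tc > self.tumor_min_tc).astype(int)
        return (tc >= self.tumor_min_tc).astype(int)

    def excluded_mask(self, tc: np.ndarray) -> np.ndarray:
        if self.exclusion is None:
            return np.zeros(tc.shape, dtype=bool)
        low, high, inclusive = self.exclusion
        upper = tc <= high if inclusive else tc < high
        return (tc > low) & upper


SCHEMES: dict[str, Scheme] = {
    "tumor_ge5": Scheme("tumor_ge5", tumor_min_tc=5.0, tumor_strict=False),
    "tumor_gt0": Scheme("tumor_gt0", tumor_min_tc=0.0, tumor_strict=True),
    "tumor_gt0_excl_lt5": Scheme(
        "tumor_gt0_excl_lt5",
        tumor_min_tc=0.0,
        tumor_strict=True,
        exclusion=(0.0, 5.0, False),
    ),
    "tumor_gt0_excl_le5": Scheme(
        "tumor_gt0_excl_le5",
        tumor_min_tc=0.0,
        tumor_strict=True,
        exclusion=(0.0, 5.0, True),
    ),
}


@dataclass
class SchemeReport:
    """Classification result for one scheme, mirroring the study's table."""

    scheme: str
    accuracy_pct: int  # rounded half-up, as displayed
    sensitivity_pct: int
    specificity_pct: int
    accuracy: float  # raw fractions
    sensitivity: float
    specificity: float
    n_samples: int
    n_train_eligible: int
    n_excluded: int
    chosen_A: np.ndarray
    dcv: DCVResult
    permutation_p: float | None = None

    def to_row(self) -> dict:
        return {
            "scheme": self.scheme,
            "correct_classification_pct": self.accuracy_pct,
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "n_samples": self.n_samples,
            "n_train_eligible": self.n_train_eligible,
            "n_excluded": self.n_excluded,
            "median_A": float(np.median(self.chosen_A)),
            "permutation_p": self.permutation_p,
        }


def _round_half_up_pct(x: float) -> int:
    return int(np.floor(100.0 * x + 0.5))


def get_scheme(name: str) -> Scheme:
    try:
        return SCHEMES[name]
    except KeyError:
        raise ValueError(
            f"unknown scheme {name!r}; valid schemes: {sorted(SCHEMES)}"
        ) from None


def assign_labels(
    metadata: pd.DataFrame, scheme: Scheme | str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Compute (labels, train_mask, test_mask) for a metadata table.

    Labels are the *test* labels: excluded samples carry the scheme's
    test label (tumor).  ``train_mask`` marks samples eligible for model
    fitting; ``test_mask`` is all-true — every sample is scored when its
    patient is held out.
    """
    scheme = get_scheme(scheme) if isinstance(scheme, str) else scheme
    validate_metadata(metadata)
    tc = metadata["tumor_content_pct"].to_numpy(dtype=float)
    labels = scheme.labels(tc)
    excluded = scheme.excluded_mask(tc)
    labels = np.where(excluded, scheme.excluded_test_label, labels)
    train_mask = ~excluded
    test_mask = np.ones(tc.size, dtype=bool)
    return labels, train_mask, test_mask


def choline_subset(spectra: SpectrumSet) -> SpectrumSet:
    """Restrict spectra to the choline-metabolite window (3.252-3.196 ppm)."""
    upper, lower = CHOLINE_WINDOW
    mask = spectra.window_mask(upper, lower)
    if not mask.any():
        raise ValueError(
            f"choline window ({upper}, {lower}) ppm contains no grid points"
        )
    return spectra.take_variables(mask)


def run_scheme(
    spectra: SpectrumSet,
    metadata: pd.DataFrame,
    scheme: Scheme | str,
    dcv_config: DCVConfig | None = None,
    rng: np.random.Generator | int | None = None,
    n_perm: int = 0,
) -> SchemeReport:
    """Evaluate one labeling scheme by patient-grouped double CV.

    Expects preprocessed spectra.  Training-excluded samples are scored
    by every outer model in whose held-out patient set they fall, so
    the no-leakage contract holds for them too.  ``n_perm > 0`` adds a
    permutation p-value (re-running the double CV per permutation).
    """
    scheme = get_scheme(scheme) if isinstance(scheme, str) else scheme
    dcv_config = dcv_config or DCVConfig()
    spectra, meta = join(spectra, metadata)
    labels, train_mask, _ = assign_labels(meta, scheme)
    train_labels = scheme.labels(meta["tumor_content_pct"].to_numpy(float))
    groups = meta["patient_id"].to_numpy()
    rng = (
        rng
        if isinstance(rng, np.random.Generator)
        else np.random.default_rng(dcv_config.seed if rng is None else rng)
    )
    result = double_cv(
        spectra.intensities,
        train_labels,
        groups,
        dcv_config,
        rng,
        train_mask=train_mask,
        y_test=labels,
    )
    p_value = None
    if n_perm > 0:
        p_value = permutation_test(
            spectra.intensities,
            train_labels,
            groups,
            dcv_config,
            n_perm=n_perm,
            rng=rng,
            train_mask=train_mask,
            y_test=labels,
        ).p_value
    n_excluded = int((~train_mask).sum())
    return SchemeReport(
        scheme=scheme.name,
        accuracy_pct=_round_half_up_pct(result.mean_accuracy),
        sensitivity_pct=_round_half_up_pct(result.mean_sensitivity),
        specificity_pct=_round_half_up_pct(result.mean_specificity),
        accuracy=result.mean_accuracy,
        sensitivity=result.mean_sensitivity,
        specificity=result.mean_specificity,
        n_samples=spectra.n_samples,
        n_train_eligible=int(train_mask.sum()),
        n_excluded=n_excluded,
        chosen_A=result.chosen_A,
        dcv=result,
        permutation_p=p_value,
    )


def report_table(reports: list[SchemeReport]) -> pd.DataFrame:
    """Stack scheme reports into one table (one row per scheme)."""
    return pd.DataFrame([r.to_row() for r in reports])


def loading_report(
    model: PLSModel | PCAResult,
    ppm: np.ndarray,
    top_k: int = 0,
    peaks: list[MetabolitePeak] | None = None,
    annotate_tol: float = 0.01,
) -> pd.DataFrame:
    """Per-variable loading (and VIP, for PLS) table with ppm annotation.

    Rows carry the ppm position, the loading value of each component,
    the VIP score (PLS models only) and, when a peak library is given,
    the name of the nearest metabolite resonance within
    ``annotate_tol`` ppm.  ``top_k > 0`` keeps the top_k rows by VIP
    (PLS) or |loading 1| (PCA); ``top_k = 0`` returns the full table in
    axis order.
    """
    ppm = np.asarray(ppm, dtype=float)
    if isinstance(model, PLSModel):
        loadings = model.P
        vip = vip_scores(model)
        rank_key = vip
        prefix = "lv"
    else:
        loadings = model.loadings
        vip = None
        rank_key = np.abs(loadings[:, 0])
        prefix = "pc"
    if loadings.shape[0] != ppm.size:
        raise ValueError("loading rows must match ppm axis length")
    data: dict[str, np.ndarray] = {"ppm": ppm}
    for a in range(loadings.shape[1]):
        data[f"{prefix}{a + 1}_loading"] = loadings[:, a]
    if vip is not None:
        data["vip"] = vip
    df = pd.DataFrame(data)
    if peaks is None:
        peaks = default_peak_library()
    positions: list[tuple[float, str]] = [
        (pos, pk.name) for pk in peaks for pos in pk.positions
    ]
    pos_arr = np.array([p for p, _ in positions])
    names = [n for _, n in positions]
    nearest = np.argmin(np.abs(ppm[:, None] - pos_arr[None, :]), axis=1)
    dist = np.abs(ppm - pos_arr[nearest])
    df["metabolite"] = [
        names[j] if d <= annotate_tol else "" for j, d in zip(nearest, dist)
    ]
    if top_k > 0:
        df = df.iloc[np.argsort(-rank_key)[:top_k]].reset_index(drop=True)
    return df
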