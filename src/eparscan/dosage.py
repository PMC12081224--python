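"""Intensity-based dosage screen for ePAR and X-deletion carriers.

The screen normalizes each sample's fluorescence over the informative
X markers of the 113-kb interval against the female cohort (median of
deviation from the per-marker female median), fits empirical reference
bands for the haploid and diploid dosage classes, and calls each sample:
a male whose normalized intensity sits in the diploid (female-like) band
is a putative ePAR carrier, one far below the haploid band a putative
deletion hemizygote; females are called reciprocally.  Samples with an
uneven sex-chromosome balance (e.g. aneuploidies) are excluded first via
median log2 ratios over non-PAR X and Y flank markers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .simdata import EPAR_INTERVAL, X_FLANK, Y_FLANK

__all__ = [
    "ReferenceBands",
    "DosageScreen",
    "sex_balance_filter",
    "normalize_intensities",
    "build_reference_bands",
    "classify_samples",
    "incidence_summary",
    "rate_percent",
]

CALL_CLASSES = (
    "REF", "EPAR", "DEL_HEMI", "HET_DEL", "HOM_DEL",
    "UNCLASSIFIED", "EXCLUDED_IMBALANCE",
)


@dataclass(frozen=True)
class ReferenceBands:
    """Closed intensity intervals for the three dosage classes.

    ``haploid_band`` and ``diploid_band`` are central 95% intervals of
    the reference males and females; ``deletion_band`` is a configured
    interval below the haploid band, half-open at the top (a value equal
    to the haploid lower endpoint is haploid).  ``provenance`` records
    the reference counts used.
    """

    haploid_band: tuple[float, float]
    diploid_band: tuple[float, float]
    deletion_band: tuple[float, float]
    provenance: dict

    def __post_init__(self):
        d_hi = self.deletion_band[1]
        h_lo, h_hi = self.haploid_band
        dip_lo, dip_hi = self.diploid_band
        if not (d_hi <= h_lo <= h_hi < dip_lo <= dip_hi):
            raise ValueError(
                "reference bands are not ordered deletion < haploid < diploid: "
                f"deletion={self.deletion_band}, haploid={self.haploid_band}, "
                f"diploid={self.diploid_band}"
            )


def _central_95(values: np.ndarray, method: str) -> tuple[float, float]:
    """Central 95% interval; nearest-rank order statistics by default."""
    values = np.sort(np.asarray(values, dtype=float))
    n = len(values)
    if method == "percentile":
        lower = values[int(np.ceil(0.025 * n)) - 1]
        upper = values[int(np.ceil(0.975 * n)) - 1]
    elif method == "gaussian":
        m, s = values.mean(), values.std(ddof=1)
        lower, upper = m - 1.96 * s, m + 1.96 * s
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return float(lower), float(upper)


def sex_balance_filter(
    intensities: pd.DataFrame,
    markers: pd.DataFrame,
    sex: pd.Series,
    threshold: float = 0.35,
    pseudocount: float | None = None,
) -> pd.Series:
    """Flag samples with balanced sex-chromosome dosage.

    For each sample the median log2 ratio against the sex-matched
    reference median is computed separately over the X-flank and Y-flank
    markers; PAR-associated markers (and the screened interval itself)
    are excluded.  A sample passes iff both medians lie within
    +-``threshold``.  ``pseudocount`` stabilizes ratios where a class
    sits near zero intensity (females on Y markers); the default is a
    quarter of the overall flank-marker median, i.e. roughly a quarter
    copy-signal unit.  Pass 0 for raw ratios.
    """
    flank_x = markers.loc[markers["region"] == X_FLANK, "marker_id"]
    flank_y = markers.loc[markers["region"] == Y_FLANK, "marker_id"]
    if flank_x.empty and flank_y.empty:
        raise ValueError("no non-PAR flank markers available for the balance "
                         "filter")
    if pseudocount is None:
        flank_all = flank_x.tolist() + flank_y.tolist()
        pseudocount = 0.25 * float(
            intensities[flank_all].clip(lower=0.0).median(axis=None)
        )
    passes = pd.Series(True, index=intensities.index, name="balance_pass")
    for sex_label in ("M", "F"):
        group = intensities.index[sex.loc[intensities.index] == sex_label]
        if group.empty:
            continue
        for marker_ids in (flank_x, flank_y):
            if marker_ids.empty:
                continue
            block = intensities.loc[group, marker_ids.tolist()]
            ref = block.median(axis=0)
            ratio = np.log2(
                (block.clip(lower=0.0) + pseudocount)
                / (ref.clip(lower=0.0) + pseudocount)
            )
            passes.loc[group] &= ratio.median(axis=1).abs() <= threshold
    return passes


def normalize_intensities(
    intensities: pd.DataFrame,
    female_ids: pd.Index | list[str],
    informative_markers: list[str],
) -> pd.Series:
    """Median-of-deviation-from-the-female-median normalization.

    Per informative marker the deviation is the sample value minus that
    marker's female median; the sample's normalized value is the median
    of its deviations.  Markers whose female median is undefined are
    excluded with a warning.  On this scale a normal female sits near 0
    and each missing copy shifts a sample down by one copy-signal unit.
    """
    female_ids = pd.Index(female_ids)
    if female_ids.empty:
        raise ValueError("at least one female is required to define the "
                         "reference medians")
    if not informative_markers:
        raise ValueError("informative marker set is empty")
    block = intensities[list(informative_markers)]
    medians = block.loc[block.index.intersection(female_ids)].median(axis=0)
    bad = medians.index[medians.isna()]
    if len(bad):
        warnings.warn(
            f"excluding {len(bad)} informative markers with undefined female "
            f"median: {list(bad)[:5]}...",
            stacklevel=2,
        )
        block = block.drop(columns=bad)
        medians = medians.drop(bad)
    deviations = block.sub(medians, axis=1)
    return deviations.median(axis=1).rename("normalized")


def build_reference_bands(
    values: pd.Series,
    sex: pd.Series,
    min_reference: int = 40,
    ci_method: str = "percentile",
    deletion_band: tuple[float, float] | None = None,
) -> ReferenceBands:
    """Fit haploid/diploid reference bands from normalized intensities.

    A single bootstrap pass assigns provisional reference samples by the
    nearest dosage center (male and female medians anchor the 1- and
    2-copy centers, their difference the copy-signal unit), then takes
    central 95% nearest-rank intervals per class.  The deletion band
    defaults to a data-driven interval centred on the extrapolated
    0-copy level, detached from the haploid band so boundary haploid
    samples are not mistaken for deletions, and non-degenerate even at
    negligible noise.
    """
    values = values.astype(float)
    sex = sex.loc[values.index]
    male_vals = values[sex == "M"]
    female_vals = values[sex == "F"]
    if len(male_vals) < min_reference or len(female_vals) < min_reference:
        raise ValueError(
            f"need at least {min_reference} reference samples per band, got "
            f"{len(male_vals)} males / {len(female_vals)} females"
        )
    c1 = float(male_vals.median())
    c2 = float(female_vals.median())
    unit = c2 - c1
    if unit <= 0:
        raise ValueError(
            "female median does not exceed male median; dosage centers "
            "cannot be anchored"
        )
    c0 = c1 - unit
    centers = np.array([c0, c1, c2])

    def nearest(vals: pd.Series) -> np.ndarray:
        return np.abs(vals.to_numpy()[:, None] - centers[None, :]).argmin(axis=1)

    male_ref = male_vals[nearest(male_vals) == 1]
    female_ref = female_vals[nearest(female_vals) == 2]
    if len(male_ref) < min_reference or len(female_ref) < min_reference:
        raise ValueError(
            f"fewer than {min_reference} provisional reference samples per "
            "band after nearest-center assignment"
        )
    haploid = _central_95(male_ref.to_numpy(), ci_method)
    diploid = _central_95(female_ref.to_numpy(), ci_method)
    if deletion_band is None:
        hap_mid = 0.5 * (haploid[0] + haploid[1])
        dip_mid = 0.5 * (diploid[0] + diploid[1])
        zero_copy = hap_mid - (dip_mid - hap_mid)
        half = max(1.5 * (haploid[1] - haploid[0]), 0.15 * (dip_mid - hap_mid))
        deletion_band = (zero_copy - half, zero_copy + half)
    bands = ReferenceBands(
        haploid_band=haploid,
        diploid_band=diploid,
        deletion_band=deletion_band,
        provenance={
            "n_reference_males": int(len(male_ref)),
            "n_reference_females": int(len(female_ref)),
            "ci_method": ci_method,
            "centers": centers.tolist(),
        },
    )
    return bands


def classify_samples(
    values: pd.Series,
    bands: ReferenceBands,
    sex: pd.Series,
    balance_pass: pd.Series | None = None,
) -> pd.DataFrame:
    """Assign every sample exactly one dosage call.

    Males: haploid band -> REF, diploid -> EPAR, deletion -> DEL_HEMI;
    females: diploid -> REF, haploid -> HET_DEL, deletion -> HOM_DEL;
    anything else UNCLASSIFIED; balance failures EXCLUDED_IMBALANCE.
    """
    sex = sex.loc[values.index]
    if balance_pass is None:
        balance_pass = pd.Series(True, index=values.index)
    balance_pass = balance_pass.loc[values.index]
    h_lo, h_hi = bands.haploid_band
    d_lo, d_hi = bands.diploid_band
    del_lo, del_hi = bands.deletion_band
    v = values.to_numpy(dtype=float)
    in_haploid = (v >= h_lo) & (v <= h_hi)
    in_diploid = (v >= d_lo) & (v <= d_hi)
    in_deletion = (v >= del_lo) & (v < del_hi)
    male = (sex == "M").to_numpy()
    call = np.where(
        male,
        np.select(
            [in_haploid, in_diploid, in_deletion],
            ["REF", "EPAR", "DEL_HEMI"],
            default="UNCLASSIFIED",
        ),
        np.select(
            [in_diploid, in_haploid, in_deletion],
            ["REF", "HET_DEL", "HOM_DEL"],
            default="UNCLASSIFIED",
        ),
    )
    call = np.where(balance_pass.to_numpy(), call, "EXCLUDED_IMBALANCE")
    return pd.DataFrame({
        "sample_id": values.index,
        "sex": sex.to_numpy(),
        "normalized_value": v,
        "balance_pass": balance_pass.to_numpy(),
        "call": call,
    }).set_index("sample_id")


def rate_percent(count: int, denominator: int, digits: int | None = None) -> float:
    """Incidence as a percentage; optional presentation rounding."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    pct = 100.0 * count / denominator
    return round(pct, digits) if digits is not None else pct


def incidence_summary(calls: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages per call class per sex.

    The percentage denominator is the number of non-excluded samples of
    the same sex; raw ratios are retained unrounded.
    """
    if calls.empty:
        raise ValueError("no calls to summarize")
    rows = []
    for sex_label, group in calls.groupby("sex"):
        informative = group[group["call"] != "EXCLUDED_IMBALANCE"]
        denom = len(informative)
        for call_class in CALL_CLASSES:
            count = int((group["call"] == call_class).sum())
            if call_class == "EXCLUDED_IMBALANCE":
                pct = np.nan
            else:
                pct = rate_percent(count, denom) if denom else np.nan
            rows.append((sex_label, call_class, count, denom, pct))
    return pd.DataFrame(
        rows, columns=["sex", "call", "count", "denominator", "percent"]
    )


class DosageScreen(BaseEstimator):
    """Scikit-learn style estimator wrapping the full dosage screen.

    ``fit`` learns the female reference medians and the dosage bands from
    a cohort; ``predict`` returns per-sample dosage calls.  Parameters
    follow the estimator convention (set in ``__init__``, fitted state in
    trailing-underscore attributes), so the screen composes with sklearn
    model-selection utilities.
    """

    def __init__(
        self,
        balance_threshold: float = 0.35,
        min_reference: int = 40,
        ci_method: str = "percentile",
        deletion_band: tuple[float, float] | None = None,
        pseudocount: float | None = None,
    ):
        self.balance_threshold = balance_threshold
        self.min_reference = min_reference
        self.ci_method = ci_method
        self.deletion_band = deletion_band
        self.pseudocount = pseudocount

    def fit(self, intensities: pd.DataFrame, sex: pd.Series, markers: pd.DataFrame):
        """Learn medians, balance flags and reference bands from a cohort."""
        informative = markers.loc[
            markers["region"] == EPAR_INTERVAL, "marker_id"
        ].tolist()
        female_ids = intensities.index[sex.loc[intensities.index] == "F"]
        self.informative_markers_ = informative
        self.markers_ = markers
        self.balance_pass_ = sex_balance_filter(
            intensities, markers, sex,
            threshold=self.balance_threshold, pseudocount=self.pseudocount,
        )
        self.female_medians_ = (
            intensities.loc[
                intensities.index.intersection(female_ids), informative
            ].median(axis=0)
        )
        values = normalize_intensities(intensities, female_ids, informative)
        fit_mask = self.balance_pass_
        self.bands_ = build_reference_bands(
            values[fit_mask], sex[fit_mask],
            min_reference=self.min_reference,
            ci_method=self.ci_method,
            deletion_band=self.deletion_band,
        )
        self.normalized_ = values
        self.sex_ = sex.loc[values.index]
        return self

    def predict(
        self,
        intensities: pd.DataFrame | None = None,
        sex: pd.Series | None = None,
    ) -> pd.DataFrame:
        """Dosage calls for new samples (default: the fitted cohort)."""
        if not hasattr(self, "bands_"):
            raise RuntimeError("DosageScreen is not fitted")
        if intensities is None:
            values, sex_s, balance = self.normalized_, self.sex_, self.balance_pass_
        else:
            if sex is None:
                raise ValueError("sex labels are required with new intensities")
            block = intensities[self.female_medians_.index.tolist()]
            values = block.sub(self.female_medians_, axis=1).median(axis=1)
            balance = sex_balance_filter(
                intensities, self.markers_, sex,
                threshold=self.balance_threshold, pseudocount=self.pseudocount,
            )
            sex_s = sex.loc[values.index]
        return classify_samples(values, self.bands_, sex_s, balance)

    def fit_predict(
        self, intensities: pd.DataFrame, sex: pd.Series, markers: pd.DataFrame
    ) -> pd.DataFrame:
        return self.fit(intensities, sex, markers).predict()
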