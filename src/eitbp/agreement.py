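"""Method-comparison statistics for paired pressure estimates.

Implements the full evaluation suite for comparing beat-by-beat pressure
estimates against an invasive reference:

- :func:`icc_31_absolute` — single-measure intraclass correlation from the
  two-way ANOVA with absolute agreement (the McGraw-Wong ICC(A,1) form),
  with the Koo & Li reliability categories;
- :func:`bland_altman_repeated` — mean bias and 1.96-SD limits of
  agreement with a one-way (subject) variance decomposition for repeated
  measurements;
- :func:`four_quadrant_concordance` — trending agreement of consecutive
  beat-to-beat changes with a central exclusion zone sized as a fraction
  of the maximal systolic change;
- :func:`error_grid_classify` — five-zone clinical risk classification
  (zones A "no risk" through E "dangerous risk") against pluggable polygon
  grids;
- :func:`summarize` — pooled report over LOSO test folds with
  density-coded scatter and histogram exports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from eitbp.core import DataError

__all__ = [
    "icc_31_absolute",
    "koo_category",
    "bland_altman_repeated",
    "BlandAltmanResult",
    "four_quadrant_concordance",
    "concordance_from_deltas",
    "ErrorGridDefinition",
    "load_error_grid",
    "default_error_grid",
    "error_grid_classify",
    "trend_profile",
    "density_bands",
    "AgreementReport",
    "summarize",
]

TARGETS = ("SAP", "MAP", "DAP")


def icc_31_absolute(reference: np.ndarray, estimate: np.ndarray) -> float:
    """Single-measure absolute-agreement ICC of two paired series.

    Two-way ANOVA with the n beats as rows and the k=2 methods as columns;
    with row, column and residual mean squares MSR, MSC, MSE the
    coefficient is::

        (MSR - MSE) / (MSR + (k-1) MSE + (k/n) (MSC - MSE))

    which penalizes systematic offsets between the methods, not only
    scatter.
    """
    x = np.column_stack(
        [np.asarray(reference, dtype=float), np.asarray(estimate, dtype=float)]
    )
    n, k = x.shape
    if n < 3:
        raise DataError("ICC needs at least 3 paired beats")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    if np.allclose(row_means.var(), 0.0):
        raise DataError("ICC undefined: no between-beat variance")
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float(
        (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
    )


def koo_category(icc: float) -> str:
    """Koo & Li reliability category for an ICC value.

    Left-closed intervals: [-inf, 0.5) poor, [0.5, 0.75) moderate,
    [0.75, 0.9) good, [0.9, 1] excellent.
    """
    if icc > 1 + 1e-9:  # allow floating-point residue at perfect agreement
        raise DataError("ICC cannot exceed 1")
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc < 0.9:
        return "good"
    return "excellent"


@dataclass
class BlandAltmanResult:
    bias: float
    loa_lower: float
    loa_upper: float
    sd_total: float
    sd_between: float
    sd_within: float
    n: int
    n_subjects: int


def bland_altman_repeated(
    reference: np.ndarray,
    estimate: np.ndarray,
    subjects: np.ndarray | None = None,
) -> BlandAltmanResult:
    """Bland-Altman bias and limits of agreement for repeated measurements.

    Differences are estimate - reference.  With multiple beats per subject
    the bias is the unweighted mean of the per-subject mean differences and
    the total SD combines the between-subject variance of those means
    (corrected for the within-subject sampling contribution) with the
    pooled within-subject variance.  LoA = bias +/- 1.96 SD.  With one
    subject (or one beat per subject) this reduces to the simple
    Bland-Altman on the raw differences.
    """
    d = np.asarray(estimate, dtype=float) - np.asarray(reference, dtype=float)
    if d.size == 0:
        raise DataError("empty input")
    if subjects is None:
        subjects = np.zeros(len(d))
    subjects = np.asarray(subjects)
    uniq = np.unique(subjects)
    groups = [d[subjects == s] for s in uniq]
    sizes = np.array([len(g) for g in groups])

    if len(uniq) == 1 or np.all(sizes == 1):
        # simple variant (single subject, or one beat per subject)
        bias = float(np.mean(d))
        sd = float(np.std(d, ddof=1)) if len(d) > 1 else 0.0
        return BlandAltmanResult(
            bias=bias,
            loa_lower=bias - 1.96 * sd,
            loa_upper=bias + 1.96 * sd,
            sd_total=sd,
            sd_between=sd,
            sd_within=0.0,
            n=len(d),
            n_subjects=len(uniq),
        )

    means = np.array([g.mean() for g in groups])
    bias = float(means.mean())
    with_var = [np.var(g, ddof=1) for g in groups if len(g) > 1]
    var_within = float(np.mean(with_var)) if with_var else 0.0
    var_means = float(np.var(means, ddof=1)) if len(means) > 1 else 0.0
    # subtract the sampling contribution of within-subject noise to the
    # spread of subject means
    var_between = max(0.0, var_means - var_within * float(np.mean(1.0 / sizes)))
    var_total = var_between + var_within
    sd = float(np.sqrt(var_total))
    return BlandAltmanResult(
        bias=bias,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        sd_total=sd,
        sd_between=float(np.sqrt(var_between)),
        sd_within=float(np.sqrt(var_within)),
        n=len(d),
        n_subjects=len(uniq),
    )


def concordance_from_deltas(
    dref: np.ndarray, dest: np.ndarray, threshold: float
) -> tuple[float, int, int]:
    """Concordance rate (%) of paired changes with a central exclusion zone.

    A pair is excluded when ``max(|dref|, |dest|) < threshold``; among the
    remaining pairs, concordant means the two changes share a sign.
    """
    dref = np.asarray(dref, dtype=float)
    dest = np.asarray(dest, dtype=float)
    keep = np.maximum(np.abs(dref), np.abs(dest)) >= threshold
    n_excluded = int(np.sum(~keep))
    dref, dest = dref[keep], dest[keep]
    if len(dref) == 0:
        raise DataError("no pairs outside the exclusion zone")
    rate = 100.0 * float(np.mean(dref * dest > 0))
    return rate, int(len(dref)), n_excluded


def four_quadrant_concordance(
    reference: np.ndarray,
    estimate: np.ndarray,
    subjects: np.ndarray | None = None,
    exclusion_frac: float = 0.10,
    anchor_ref: np.ndarray | None = None,
) -> tuple[float, int, int]:
    """4-quadrant trending concordance of consecutive beat-to-beat changes.

    Changes are differences of consecutive beats *within* a subject (no
    cross-subject pairs).  The exclusion threshold is ``exclusion_frac``
    times the maximal absolute change of the anchor series — by convention
    the systolic reference (pass ``anchor_ref``); without an anchor the
    series' own reference changes are used.
    """
    reference = np.asarray(reference, dtype=float)
    estimate = np.asarray(estimate, dtype=float)
    if subjects is None:
        subjects = np.zeros(len(reference))
    subjects = np.asarray(subjects)

    def deltas(x: np.ndarray) -> np.ndarray:
        return np.concatenate(
            [np.diff(x[subjects == s]) for s in np.unique(subjects)]
        )

    dref = deltas(reference)
    dest = deltas(estimate)
    if len(dref) == 0:
        raise DataError("need at least 2 beats within one subject")
    danchor = deltas(np.asarray(anchor_ref, dtype=float)) if anchor_ref is not None else dref
    threshold = exclusion_frac * float(np.max(np.abs(danchor)))
    return concordance_from_deltas(dref, dest, threshold)


@dataclass
class ErrorGridDefinition:
    """Named risk-zone polygons in (reference, estimate) mmHg space.

    Classification precedence is the zone order (A before B ... before E);
    polygon boundaries are inclusive.
    """

    target: str
    zones: list[tuple[str, Polygon]]
    domain: tuple[float, float]
    note: str = ""
    synthetic: bool = False

    @property
    def zone_names(self) -> list[str]:
        return [name for name, _ in self.zones]


def load_error_grid(path) -> ErrorGridDefinition:
    """Load a zone-polygon grid from JSON."""
    with open(path) as f:
        raw = json.load(f)
    zones = [
        (z["name"], Polygon(z["polygon"])) for z in raw["zones"]
    ]
    return ErrorGridDefinition(
        target=raw["target"],
        zones=zones,
        domain=tuple(raw.get("domain", (0.0, 300.0))),
        note=raw.get("note", ""),
        synthetic=bool(raw.get("synthetic", False)),
    )


def default_error_grid(target: str) -> ErrorGridDefinition:
    """The shipped synthetic approximation grid for SAP or MAP.

    No risk grid exists for DAP; requesting one raises.
    """
    target = target.upper()
    if target not in ("SAP", "MAP"):
        raise DataError(f"no error grid available for target {target!r}")
    name = f"{target.lower()}_grid_synthetic.json"
    with resources.as_file(
        resources.files("eitbp.data").joinpath(name)
    ) as p:
        return load_error_grid(p)


def error_grid_classify(
    reference: np.ndarray,
    estimate: np.ndarray,
    grid: ErrorGridDefinition,
) -> tuple[np.ndarray, dict[str, float]]:
    """Assign each (reference, estimate) pair to a risk zone.

    Returns the per-beat zone labels and the zone histogram in percent
    (sums to 100).  A point outside every polygon is a grid-configuration
    error.
    """
    reference = np.asarray(reference, dtype=float)
    estimate = np.asarray(estimate, dtype=float)
    labels = np.empty(len(reference), dtype="<U1")
    prepared = [(name, poly) for name, poly in grid.zones]
    for i, (r, e) in enumerate(zip(reference, estimate)):
        pt = Point(r, e)
        for name, poly in prepared:
            # covers() includes boundary points
            if poly.covers(pt):
                labels[i] = name
                break
        else:
            raise DataError(
                f"point (reference={r:.1f}, estimate={e:.1f}) outside all "
                f"zones of the {grid.target} grid"
            )
    hist = {
        name: 100.0 * float(np.mean(labels == name))
        for name in grid.zone_names
    }
    return labels, hist


def trend_profile(
    reference: np.ndarray,
    estimate: np.ndarray,
    times: np.ndarray,
    segment_bounds: np.ndarray | None = None,
    smooth_window: int | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Chronological (reference, estimate) profile for trending plots.

    Returns a time-sorted frame and the segment-transition times (empty if
    none given).  ``smooth_window`` optionally applies a centered rolling
    mean (beats); no smoothing by default.
    """
    df = pd.DataFrame(
        {"time": np.asarray(times, dtype=float),
         "reference": np.asarray(reference, dtype=float),
         "estimate": np.asarray(estimate, dtype=float)}
    ).sort_values("time", kind="stable").reset_index(drop=True)
    if smooth_window and smooth_window > 1:
        for col in ("reference", "estimate"):
            df[col] = df[col].rolling(smooth_window, center=True, min_periods=1).mean()
    bounds = (
        np.asarray(segment_bounds, dtype=float)
        if segment_bounds is not None
        else np.zeros(0)
    )
    return df, bounds


def density_bands(x: np.ndarray, y: np.ndarray, bins: int = 60, n_bands: int = 5) -> np.ndarray:
    """Per-point density band (1..n_bands) from a 2-D histogram.

    Band 1 holds the sparsest fifth of the occupied density range, band
    ``n_bands`` the densest — the relative-frequency coding used for
    overlap-aware scatter plots.
    """
    h, xe, ye = np.histogram2d(x, y, bins=bins)
    xi = np.clip(np.digitize(x, xe[1:-1]), 0, bins - 1)
    yi = np.clip(np.digitize(y, ye[1:-1]), 0, bins - 1)
    dens = h[xi, yi]
    edges = np.linspace(0, dens.max(), n_bands + 1)
    return np.clip(np.digitize(dens, edges[1:-1]) + 1, 1, n_bands)


@dataclass
class AgreementReport:
    """Per-target agreement summary over pooled test-fold beats."""

    target: str
    n_beats: int
    n_subjects: int
    icc: float
    icc_category: str
    bias_mmHg: float
    loa_lower_mmHg: float
    loa_upper_mmHg: float
    concordance_pct: float
    concordance_n_used: int
    concordance_n_excluded: int
    zone_fractions_pct: dict[str, float] | None = None


def summarize(
    fold_results,
    out_dir=None,
    exclusion_frac: float = 0.10,
    grids: dict[str, ErrorGridDefinition] | None = None,
) -> dict[str, AgreementReport]:
    """Pool all LOSO test folds and compute the full agreement suite.

    Produces one :class:`AgreementReport` per target (SAP, MAP, DAP; DAP
    has no error-grid entry).  With ``out_dir`` the report is written as
    JSON and CSV together with density-coded scatter plots and risk-zone
    histograms.
    """
    fold_results = list(fold_results)
    if not fold_results:
        raise DataError("no folds to summarize")
    ref = np.concatenate([f.references_mmHg for f in fold_results])
    est = np.concatenate([f.predictions_mmHg for f in fold_results])
    subj = np.concatenate(
        [np.repeat(f.test_subject_id, len(f.references_mmHg)) for f in fold_results]
    )
    if grids is None:
        grids = {t: default_error_grid(t) for t in ("SAP", "MAP")}

    reports: dict[str, AgreementReport] = {}
    for j, target in enumerate(TARGETS):
        r, e = ref[:, j], est[:, j]
        icc = icc_31_absolute(r, e)
        ba = bland_altman_repeated(r, e, subj)
        conc, n_used, n_exc = four_quadrant_concordance(
            r, e, subj, exclusion_frac=exclusion_frac, anchor_ref=ref[:, 0]
        )
        zones = None
        if target in grids:
            _, zones = error_grid_classify(r, e, grids[target])
        reports[target] = AgreementReport(
            target=target,
            n_beats=len(r),
            n_subjects=len(np.unique(subj)),
            icc=icc,
            icc_category=koo_category(icc),
            bias_mmHg=ba.bias,
            loa_lower_mmHg=ba.loa_lower,
            loa_upper_mmHg=ba.loa_upper,
            concordance_pct=conc,
            concordance_n_used=n_used,
            concordance_n_excluded=n_exc,
            zone_fractions_pct=zones,
        )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "agreement_report.json", "w") as f:
            json.dump({t: asdict(rep) for t, rep in reports.items()}, f, indent=1)
        pd.DataFrame(
            [asdict(rep) for rep in reports.values()]
        ).drop(columns="zone_fractions_pct").to_csv(
            out_dir / "agreement_report.csv", index=False
        )
        _write_plots(ref, est, reports, grids, out_dir)
    return reports


def _write_plots(ref, est, reports, grids, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(13, 4.2))
    for j, (ax, target) in enumerate(zip(axes, TARGETS)):
        bands = density_bands(ref[:, j], est[:, j])
        sc = ax.scatter(
            ref[:, j], est[:, j], c=bands, cmap="inferno", s=4, vmin=1, vmax=5
        )
        lims = [
            min(ref[:, j].min(), est[:, j].min()) - 5,
            max(ref[:, j].max(), est[:, j].max()) + 5,
        ]
        ax.plot(lims, lims, "k--", lw=0.8)
        ax.set_xlabel(f"reference {target} (mmHg)")
        ax.set_ylabel(f"estimated {target} (mmHg)")
        ax.set_title(
            f"{target}: ICC {reports[target].icc:.3f} "
            f"({reports[target].icc_category})"
        )
        fig.colorbar(sc, ax=ax, label="density band")
    fig.tight_layout()
    fig.savefig(out_dir / "scatter_density.png", dpi=120)
    plt.close(fig)

    with_zones = [t for t in TARGETS if reports[t].zone_fractions_pct]
    if with_zones:
        fig, axes = plt.subplots(1, len(with_zones), figsize=(4.5 * len(with_zones), 4))
        axes = np.atleast_1d(axes)
        for ax, target in zip(axes, with_zones):
            zf = reports[target].zone_fractions_pct
            ax.bar(list(zf.keys()), list(zf.values()), color="tab:blue")
            ax.set_ylabel("% of beats")
            ax.set_title(f"{target} risk zones")
        fig.tight_layout()
        fig.savefig(out_dir / "risk_zones.png", dpi=120)
        plt.close(fig)
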