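"""Comparative analytics between systems: delta-metrics, stabilization labels,
variant perturbation summaries, group disruption scoring, and the supporting
statistics (pooled t-test, Pearson R^2, normalizations, conservation tallies).

Sign convention for stabilization (used throughout): increases in RMSD, RMSF
and SASA are destabilizing; decreases in contacts and DCCM coupling are loss
of structural coupling and thus also destabilizing.  Deltas are always
system B minus system A (mutant minus wild type, or bound minus apo).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DeltaReport",
    "VariantRecord",
    "DisruptionReport",
    "METRIC_SIGNS",
    "CLINVAR_CLASSES",
    "delta_metrics",
    "classify_stabilization",
    "destabilization_magnitude",
    "perturbation_summary",
    "disruption_score",
    "rmsd_ttest",
    "pearson_r2",
    "normalize_ums",
    "foldability_percent",
    "conservation_classify",
    "read_alignment",
    "FOLDABILITY_MAX",
]

#: +1: an increase is destabilizing; -1: a decrease is destabilizing.
METRIC_SIGNS = {
    "rmsd_mean": +1,
    "rmsf": +1,
    "sasa_mean": +1,
    "exposure_ratio": +1,
    "contacts_mean": -1,
    "dccm_score": -1,
}

CLINVAR_CLASSES = (
    "pathogenic", "likely_pathogenic", "uncertain", "conflicting",
    "not_provided", "benign", "likely_benign",
)

FOLDABILITY_MAX = 19.0

#: |delta| below this fraction of the wild-type magnitude counts as neutral.
NEUTRAL_RELATIVE_BAND = 0.01
NEUTRAL_ABSOLUTE_FLOOR = 1e-9


@dataclass
class DeltaReport:
    """Per-residue, per-metric differences (B - A) plus the A-side baseline."""

    delta: pd.DataFrame
    wildtype: pd.DataFrame
    name: str = ""

    def metrics(self) -> list[str]:
        return [c for c in self.delta.columns if c in METRIC_SIGNS]


@dataclass
class VariantRecord:
    """One missense variant with its clinical class and analysis flags."""

    wt_aa: str
    position: int
    mut_aa: str
    clinvar_class: str = "not_provided"
    perturbation_flags: dict = field(default_factory=dict)  # analysis -> residues
    ums: float | None = None
    foldability: float | None = None

    def __post_init__(self) -> None:
        if self.position <= 0:
            raise ValueError("position must be a positive integer")
        if self.clinvar_class not in CLINVAR_CLASSES:
            raise ValueError(f"unknown ClinVar class {self.clinvar_class!r}")
        if self.ums is not None and not (0.0 <= self.ums <= 1.0):
            raise ValueError("UMS must lie in [0, 1]")

    @property
    def name(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"


@dataclass
class DisruptionReport:
    groups: dict                  # name -> residue list
    per_residue_mean: pd.Series   # mean destabilization across variants
    group_scores: dict            # name -> group-level score
    ratio: float | None           # first group / second group
    settings: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Delta computation and labeling
# ---------------------------------------------------------------------------

def delta_metrics(table_a: pd.DataFrame, table_b: pd.DataFrame,
                  name: str = "") -> DeltaReport:
    """Element-wise B - A over shared residues and metrics.

    Missing values propagate as missing, never as zero.  Raises when the two
    tables share no residues.
    """
    shared = table_a.index.intersection(table_b.index)
    if len(shared) == 0:
        raise ValueError("tables share no residues; nothing to compare")
    cols = table_a.columns.intersection(table_b.columns)
    delta = table_b.loc[shared, cols] - table_a.loc[shared, cols]
    return DeltaReport(delta=delta, wildtype=table_a.loc[shared, cols],
                       name=name)


def _neutral_band(wildtype: pd.DataFrame) -> pd.DataFrame:
    return np.maximum(
        NEUTRAL_RELATIVE_BAND * wildtype.abs(), NEUTRAL_ABSOLUTE_FLOOR
    )


def classify_stabilization(report: DeltaReport) -> pd.DataFrame:
    """Per-residue per-metric labels in {stabilizing, destabilizing, neutral}.

    Adds summary columns ``stabilized_any`` / ``destabilized_any`` (True when
    any metric moves in that direction beyond the neutral band).
    """
    metrics = report.metrics()
    band = _neutral_band(report.wildtype[metrics])
    out = pd.DataFrame(index=report.delta.index)
    for m in metrics:
        signed = report.delta[m] * METRIC_SIGNS[m]  # positive = destabilizing
        lab = pd.Series("neutral", index=report.delta.index, dtype=object)
        lab[signed > band[m]] = "destabilizing"
        lab[signed < -band[m]] = "stabilizing"
        lab[report.delta[m].isna()] = "missing"
        out[m] = lab
    out["stabilized_any"] = (out[metrics] == "stabilizing").any(axis=1)
    out["destabilized_any"] = (out[metrics] == "destabilizing").any(axis=1)
    return out


def destabilization_magnitude(report: DeltaReport) -> pd.DataFrame:
    """Dimensionless destabilization per residue per metric.

    Each delta is sign-adjusted so that positive means destabilizing, then
    divided by the wild-type magnitude of that metric for that residue
    (relative change).  Where the wild-type value is zero the fallback is a
    z-score against the wild-type spread of that metric across the residue
    universe (unit denominator if that spread is also zero).
    """
    metrics = report.metrics()
    out = pd.DataFrame(index=report.delta.index)
    for m in metrics:
        signed = report.delta[m] * METRIC_SIGNS[m]
        denom = report.wildtype[m].abs().copy()
        zero = denom <= NEUTRAL_ABSOLUTE_FLOOR
        if zero.any():
            spread = float(report.wildtype[m].std(ddof=0))
            denom[zero] = spread if spread > NEUTRAL_ABSOLUTE_FLOOR else 1.0
        out[m] = signed / denom
    return out


# ---------------------------------------------------------------------------
# Variant panel summaries
# ---------------------------------------------------------------------------

def perturbation_summary(
    variants: list[VariantRecord],
    residue_universe: list,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-variant fraction of universe residues perturbed, per analysis type.

    Rows are variants; columns are the analysis types present across the
    panel, plus ``grand_mean`` (mean across types) and ``above_threshold``
    (grand mean strictly above the threshold, default 50%).
    """
    if not residue_universe:
        raise ValueError("residue universe must be non-empty")
    universe = set(residue_universe)
    analyses = sorted({a for v in variants for a in v.perturbation_flags})
    rows = {}
    for v in variants:
        if not v.perturbation_flags:
            warnings.warn(
                f"variant {v.name} has no perturbation flags recorded",
                stacklevel=2,
            )
        row = {}
        for a in analyses:
            flagged = set(v.perturbation_flags.get(a, ())) & universe
            row[a] = len(flagged) / len(universe)
        rows[v.name] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    if analyses:
        table["grand_mean"] = table[analyses].mean(axis=1)
    else:
        table["grand_mean"] = 0.0
    table["above_threshold"] = table["grand_mean"] > threshold
    return table


def disruption_score(
    variant_deltas: list[DeltaReport],
    groups: dict | None = None,
) -> DisruptionReport:
    """Group-level mutation-disruption scores and their ratio.

    Per variant, destabilization magnitudes are averaged across metrics per
    residue; these are then averaged across variants per residue, and the
    residue-level means are averaged within each group.  The ratio of the
    first group's score to the second's quantifies relative susceptibility
    to mutation.  Default groups: the anchoring region (K334, E345, F347)
    versus the gating loop (M374, S375, Q376, V377, G379, S380, F386).
    """
    if groups is None:
        from .synthetic_data import tyrosinase_fixtures
        fx = tyrosinase_fixtures()
        groups = {"anchoring_334_347": fx.anchoring_group,
                  "gating_374_386": fx.gating_group}
    names = list(groups)
    all_members = [r for g in groups.values() for r in g]
    if len(set(all_members)) != len(all_members):
        raise ValueError("groups must be non-overlapping")
    if not variant_deltas:
        raise ValueError("at least one variant delta required")

    per_variant = []
    for rep in variant_deltas:
        mags = destabilization_magnitude(rep)
        per_variant.append(mags.mean(axis=1))  # mean across metrics
    per_res = pd.concat(per_variant, axis=1).mean(axis=1)  # across variants

    for gname, members in groups.items():
        missing = [r for r in members if r not in per_res.index]
        if missing:
            raise KeyError(
                f"group {gname!r} residues absent from all deltas: {missing}"
            )
    group_scores = {
        gname: float(per_res.loc[list(members)].mean())
        for gname, members in groups.items()
    }
    ratio = None
    if len(names) >= 2 and group_scores[names[1]] > 0:
        ratio = group_scores[names[0]] / group_scores[names[1]]
    return DisruptionReport(
        groups=dict(groups),
        per_residue_mean=per_res,
        group_scores=group_scores,
        ratio=ratio,
        settings={
            "commensuration": "sign-adjusted delta / wild-type magnitude",
            "metric_signs": dict(METRIC_SIGNS),
        },
    )


# ---------------------------------------------------------------------------
# Statistics and normalizations
# ---------------------------------------------------------------------------

def rmsd_ttest(series_a, series_b, welch: bool = False) -> tuple[float, float, str]:
    """Two-sample Student's t-test (pooled variance), two-tailed.

    Returns ``(t, p, stars)`` with stars '' / '*' / '**' / '***' at
    p < 0.05 / 0.01 / 0.001.  Degenerate zero-variance cases: equal means
    give (0, 1, ''); unequal means give an infinite-t flagged result.
    ``welch=True`` switches to the unequal-variance (Welch) form.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both series need length >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, ""
        t = np.inf if b.mean() < a.mean() else -np.inf
        return float(t), 0.0, "***"
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    stars = ""
    if p < 0.001:
        stars = "***"
    elif p < 0.01:
        stars = "**"
    elif p < 0.05:
        stars = "*"
    return float(t), float(p), stars


def pearson_r2(x, y) -> float:
    """Squared Pearson correlation, in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length series of length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def normalize_ums(raw: float) -> float:
    """Unfolding-mutation-screen score in [0, 1] expressed as a percentage."""
    if not (0.0 <= raw <= 1.0):
        raise ValueError(f"UMS value {raw} outside [0, 1]")
    return raw * 100.0


def foldability_percent(raw: float) -> float:
    """Foldability as a percentage of the maximum reference value (19)."""
    if raw < 0:
        raise ValueError(f"foldability {raw} is negative")
    pct = raw / FOLDABILITY_MAX * 100.0
    if pct > 100.0:
        warnings.warn(
            f"foldability {raw} exceeds the reference maximum "
            f"{FOLDABILITY_MAX}", stacklevel=2,
        )
    return pct


# ---------------------------------------------------------------------------
# Conservation
# ---------------------------------------------------------------------------

_AMBIGUOUS = set("BJOUXZ*")


def read_alignment(path, fmt: str | None = None) -> dict:
    """Read an aligned-FASTA or Clustal MSA into ``{id: aligned string}``.

    The format is inferred from the file when not given (Clustal files
    start with a CLUSTAL header).
    """
    from Bio import AlignIO

    if fmt is None:
        with open(path) as fh:
            first = fh.readline()
        fmt = "clustal" if first.upper().startswith("CLUSTAL") else "fasta"
    aln = AlignIO.read(path, fmt)
    return {rec.id: str(rec.seq) for rec in aln}


def conservation_classify(
    alignment,
    reference_id: str,
    vertebrate_ids,
) -> list[tuple[int, str, str]]:
    """Per-reference-position conservation class from an MSA.

    ``alignment`` is a mapping ``{sequence id: aligned string}`` or a
    Biopython ``MultipleSeqAlignment``.  For each ungapped reference
    position (1-based): ``conserved_distant`` when the column is identical
    across all rows, else ``conserved_vertebrate`` when identical across the
    vertebrate-tagged rows, else ``not_conserved``.  Gaps and ambiguity
    codes break identity.
    """
    if not isinstance(alignment, dict):
        alignment = {rec.id: str(rec.seq) for rec in alignment}
    if reference_id not in alignment:
        raise KeyError(f"reference row {reference_id!r} not in alignment")
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("ragged alignment: rows differ in length")
    vertebrates = [i for i in vertebrate_ids if i in alignment]
    ref = alignment[reference_id].upper()
    out = []
    pos = 0
    for col in range(len(ref)):
        c = ref[col]
        if c == "-":
            continue
        pos += 1

        def identical(ids) -> bool:
            chars = {alignment[i][col].upper() for i in ids}
            if len(chars) != 1:
                return False
            ch = next(iter(chars))
            return ch != "-" and ch not in _AMBIGUOUS

        if identical(list(alignment)):
            cls = "conserved_distant"
        elif identical(vertebrates):
            cls = "conserved_vertebrate"
        else:
            cls = "not_conserved"
        out.append((pos, c, cls))
    return out
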