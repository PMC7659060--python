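"""Stage 5 — expression analysis for root nodule symbiosis (RNS).

Covers: geNorm reference-gene stability from qPCR Ct tables,
efficiency-corrected relative expression against a baseline timepoint
(generalizing 2^−ΔΔCt to arbitrary amplification efficiency E), temporal
pattern classification over the nodule time course, high-expression
candidate selection across tissue classes, and the log/centering transform
used for heatmap display.

Relative quantities follow Q = E^(Ct_min − Ct); normalization divides by the
geometric mean of the reference-gene quantities per sample.  The geNorm
stability M of a candidate reference is the mean, over the other candidates,
of the standard deviation across samples of the log2 quantity ratio — lower
is more stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from famsurvey.io_formats import ValidationError

SAMPLE_CLASSES = ("symbiosis_tissue", "nodule_stage")

PATTERN_CLASSES = (
    "senescence_up",
    "development_down",
    "mid_peak",
    "down_then_up",
    "up_then_down",
    "bimodal",
    "flat",
)


@dataclass
class ExpressionMatrix:
    """Genes × samples abundance matrix with a tissue class per sample."""

    values: pd.DataFrame  # index: gene ids, columns: sample ids
    sample_class: dict[str, str]  # sample -> symbiosis_tissue | nodule_stage

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate gene ids in expression matrix")
        if (self.values.values < 0).any():
            raise ValidationError("negative expression values")
        unknown = set(self.values.columns) - set(self.sample_class)
        if unknown:
            raise ValidationError(
                f"samples without tissue class: {sorted(unknown)[:5]}"
            )
        bad = set(self.sample_class.values()) - set(SAMPLE_CLASSES)
        if bad:
            raise ValidationError(f"unknown tissue classes: {sorted(bad)}")

    def samples_of(self, tissue_class: str) -> list[str]:
        return [
            s for s in self.values.columns
            if self.sample_class[s] == tissue_class
        ]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "#class\t"
                + "\t".join(self.sample_class[s] for s in self.values.columns)
                + "\n"
            )
            self.values.to_csv(fh, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#class"):
                raise ValidationError(
                    f"{path}: missing '#class' sample-annotation line"
                )
            classes = header.rstrip("\n").split("\t")[1:]
            df = pd.read_csv(fh, sep="\t", index_col="gene_id")
        return cls(values=df, sample_class=dict(zip(df.columns, classes)))


@dataclass
class QpcrTable:
    """Long-format qPCR table: one row per technical replicate."""

    data: pd.DataFrame  # gene_id, sample_id, replicate, ct, efficiency

    REQUIRED = ("gene_id", "sample_id", "replicate", "ct", "efficiency")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.data.columns)
        if missing:
            raise ValidationError(f"qPCR table missing columns {sorted(missing)}")
        if (self.data["ct"] <= 0).any():
            raise ValidationError("Ct values must be positive")
        eff = self.data["efficiency"]
        if ((eff <= 1) | (eff > 2)).any():
            raise ValidationError("amplification efficiency must be in (1, 2]")

    def mean_ct(self) -> pd.DataFrame:
        """Mean and SD of Ct per (gene, sample), plus efficiency."""
        grouped = self.data.groupby(["gene_id", "sample_id"])
        out = grouped.agg(
            ct=("ct", "mean"), ct_sd=("ct", "std"),
            efficiency=("efficiency", "first"), n=("ct", "size"),
        ).reset_index()
        out["ct_sd"] = out["ct_sd"].fillna(0.0)
        return out

    def quantities(self) -> pd.DataFrame:
        """Relative quantities Q = E^(Ct_min − Ct) per gene across samples."""
        mean = self.mean_ct()
        mins = mean.groupby("gene_id")["ct"].transform("min")
        mean["quantity"] = mean["efficiency"] ** (mins - mean["ct"])
        return mean

    def genes(self) -> list[str]:
        return sorted(self.data["gene_id"].unique())

    def samples(self) -> list[str]:
        return list(pd.unique(self.data["sample_id"]))

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "QpcrTable":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class StabilityResult:
    """geNorm stability of one candidate reference gene (lower M = stabler)."""

    gene_id: str
    M: float
    rank: int

    def __post_init__(self) -> None:
        if self.M < 0:
            raise ValidationError("geNorm M must be non-negative")


@dataclass
class PatternCall:
    """Temporal expression class over the nodule time course."""

    gene_id: str
    pattern: str
    peak_timepoint: int  # index into the ordered timepoints

    def __post_init__(self) -> None:
        if self.pattern not in PATTERN_CLASSES:
            raise ValidationError(f"unknown pattern class {self.pattern!r}")


# ---------------------------------------------------------------------------
# geNorm
# ---------------------------------------------------------------------------


def genorm_stability(
    qpcr: QpcrTable, candidate_references: Sequence[str]
) -> list[StabilityResult]:
    """Rank candidate reference genes by geNorm stability M.

    M_j = mean over the other candidates k of the standard deviation (across
    samples, ddof=1) of log2(Q_j / Q_k).  Candidates missing in any sample
    are an error.
    """
    if len(candidate_references) < 2:
        raise ValidationError("geNorm needs at least 2 candidate references")
    q = qpcr.quantities()
    samples = qpcr.samples()
    if len(samples) < 2:
        raise ValidationError("geNorm needs at least 2 samples")
    per_gene: dict[str, np.ndarray] = {}
    for gene in candidate_references:
        sub = q[q["gene_id"] == gene].set_index("sample_id")["quantity"]
        missing = set(samples) - set(sub.index)
        if missing:
            raise ValidationError(
                f"candidate {gene} missing in samples {sorted(missing)[:5]}"
            )
        per_gene[gene] = sub.loc[samples].to_numpy(dtype=float)

    ms: list[tuple[str, float]] = []
    for gene in candidate_references:
        sds = []
        for other in candidate_references:
            if other == gene:
                continue
            ratios = np.log2(per_gene[gene] / per_gene[other])
            sds.append(float(np.std(ratios, ddof=1)))
        ms.append((gene, float(np.mean(sds))))
    ranked = sorted(ms, key=lambda item: (item[1], item[0]))
    return [
        StabilityResult(gene_id=gene, M=m, rank=rank)
        for rank, (gene, m) in enumerate(ranked, start=1)
    ]


# ---------------------------------------------------------------------------
# relative expression
# ---------------------------------------------------------------------------


def relative_expression(
    qpcr: QpcrTable,
    target: str,
    references: Sequence[str],
    baseline_sample: str,
) -> pd.DataFrame:
    """Efficiency-corrected fold changes of ``target`` vs a baseline sample.

    Per sample the target quantity is divided by the geometric mean of the
    reference quantities; fold change is that normalized value relative to
    the baseline sample (baseline ≡ 1).  With E = 2 throughout this equals
    the classic 2^−ΔΔCt.  Replicate Ct scatter is propagated to a fold-change
    SD by first-order error propagation.
    """
    q = qpcr.quantities().set_index(["gene_id", "sample_id"])
    samples = qpcr.samples()
    if baseline_sample not in samples:
        raise ValidationError(f"baseline sample {baseline_sample!r} not present")
    for gene in [target, *references]:
        for sample in samples:
            if (gene, sample) not in q.index:
                raise ValidationError(f"{gene} has no Ct in sample {sample}")

    def norm_factor(sample: str) -> float:
        quantities = [q.loc[(r, sample), "quantity"] for r in references]
        if any(value <= 0 for value in quantities):
            raise ValidationError(f"zero reference quantity in {sample}")
        return float(np.exp(np.mean(np.log(quantities))))

    def log_var(gene: str, sample: str) -> float:
        # Var[ln Q] ≈ (ln E · sd_Ct)², replicate-mean SD
        row = q.loc[(gene, sample)]
        n = max(int(row["n"]), 1)
        return (math.log(row["efficiency"]) * row["ct_sd"]) ** 2 / n

    base_norm = q.loc[(target, baseline_sample), "quantity"] / norm_factor(
        baseline_sample
    )
    rows = []
    for sample in samples:
        value = q.loc[(target, sample), "quantity"] / norm_factor(sample)
        fold = 1.0 if sample == baseline_sample else float(value / base_norm)
        if sample == baseline_sample:
            sd = 0.0
        else:
            var = log_var(target, sample) + log_var(target, baseline_sample)
            k = len(references)
            for ref in references:
                var += (log_var(ref, sample) + log_var(ref, baseline_sample)) / k**2
            sd = fold * math.sqrt(var)
        rows.append({"sample_id": sample, "fold_change": fold, "sd": sd})
    return pd.DataFrame(rows, columns=["sample_id", "fold_change", "sd"])


# ---------------------------------------------------------------------------
# temporal pattern classification
# ---------------------------------------------------------------------------


def _local_maxima(values: Sequence[float]) -> list[int]:
    idx = []
    n = len(values)
    for i in range(n):
        left = values[i - 1] if i > 0 else -math.inf
        right = values[i + 1] if i < n - 1 else -math.inf
        if values[i] > left and values[i] > right:
            idx.append(i)
    return idx


def classify_pattern(
    fold_changes: Sequence[float],
    fc_threshold: float = 2.0,
    gene_id: str = "",
) -> PatternCall:
    """Classify a nodule time-course profile into a temporal class.

    ``fold_changes`` are ordered by timepoint, relative to the first
    timepoint.  A significant move between consecutive points is a ratio
    ≥ ``fc_threshold`` (rise) or ≤ 1/``fc_threshold`` (fall).  Classes are
    tried in priority order:

    - senescence_up: at least one rise, no fall, global maximum at the last
      timepoint;
    - development_down: at least one fall, no rise;
    - mid_peak: global maximum at an early interior timepoint (the 30/42dN
      analogs — interior indices in the first half of the course) with a
      significant fall after it;
    - down_then_up: first significant move a fall, a later significant rise;
    - up_then_down: first significant move a rise, a later significant fall,
      maximum not at the last timepoint;
    - bimodal: both a significant rise and a significant fall present, and
      two or more local maxima each within ``fc_threshold`` of the global
      maximum;
    - flat: no significant move.

    The class is invariant to rescaling all fold changes by a constant.
    """
    values = [float(v) for v in fold_changes]
    n = len(values)
    if n < 3:
        raise ValidationError("need at least 3 timepoints")
    if any(v <= 0 for v in values):
        raise ValidationError("fold changes must be positive")
    if fc_threshold <= 1:
        raise ValidationError("fc_threshold must be > 1")

    moves = []  # +1 rise, -1 fall, 0 none, between consecutive points
    for prev, nxt in zip(values, values[1:]):
        ratio = nxt / prev
        if ratio >= fc_threshold:
            moves.append(1)
        elif ratio <= 1.0 / fc_threshold:
            moves.append(-1)
        else:
            moves.append(0)
    rises = [i for i, m in enumerate(moves) if m == 1]
    falls = [i for i, m in enumerate(moves) if m == -1]
    peak = max(range(n), key=lambda i: (values[i], -i))
    early_interior = range(1, (n - 1) // 2 + 1)

    def call(pattern: str) -> PatternCall:
        return PatternCall(gene_id=gene_id, pattern=pattern, peak_timepoint=peak)

    if rises and not falls and peak == n - 1:
        return call("senescence_up")
    if falls and not rises:
        return call("development_down")
    if peak in early_interior and any(f >= peak for f in falls):
        return call("mid_peak")
    if rises and falls and falls[0] < rises[0] and rises[-1] > falls[0]:
        return call("down_then_up")
    if rises and falls and rises[0] < falls[0] and falls[-1] > rises[0] \
            and peak != n - 1:
        return call("up_then_down")
    if rises and falls:
        maxima = _local_maxima(values)
        near_top = [
            i for i in maxima if values[i] >= values[peak] / fc_threshold
        ]
        if len(near_top) >= 2:
            return call("bimodal")
    if not rises and not falls:
        return call("flat")
    # fallthrough for profiles outside the designed shapes
    if peak == n - 1:
        return call("senescence_up")
    if 0 < peak < n - 1:
        return call("mid_peak" if falls else "up_then_down")
    return call("development_down")


# ---------------------------------------------------------------------------
# candidate selection and heatmap transform
# ---------------------------------------------------------------------------


def select_rns_candidates(
    matrix: ExpressionMatrix, high_quantile: float = 0.75
) -> set[str]:
    """Genes highly expressed in ≥1 symbiosis tissue AND ≥1 nodule sample.

    "Highly expressed" = strictly above the per-sample ``high_quantile``
    quantile computed over genes.
    """
    if not 0 < high_quantile < 1:
        raise ValidationError("high_quantile must be in (0, 1)")
    for tissue_class in SAMPLE_CLASSES:
        if not matrix.samples_of(tissue_class):
            raise ValidationError(f"no samples of class {tissue_class!r}")
    thresholds = matrix.values.quantile(high_quantile, axis=0)
    high = matrix.values.gt(thresholds, axis=1)
    symbiosis = high[matrix.samples_of("symbiosis_tissue")].any(axis=1)
    nodule = high[matrix.samples_of("nodule_stage")].any(axis=1)
    return set(matrix.values.index[symbiosis & nodule])


def heatmap_matrix(
    matrix: ExpressionMatrix,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """log2(value + 1) then per-gene (row) centering, for heatmap display."""
    transformed = np.log2(matrix.values + 1.0)
    centered = transformed.sub(transformed.mean(axis=1), axis=0)
    meta = {"transform": "log2(x+1), row-centered"}
    return centered, meta
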