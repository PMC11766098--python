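"""Flow-cell run comparison statistics.

A sequencing experiment mixes one high-capacity MinION flow-cell (MIN)
with several small Flongle flow-cells (FLG) on the same DNA library.
This module compares the two formats: one-sample t-tests of the FLG
replicate values against the single MIN value taken as the reference,
paired t-tests between matched conditions (e.g. fast vs sup
basecalling), a two-way repeated-measures ANOVA, and the derived
throughput summary (shares of bases / reads / input DNA, per-pore
output).

Read and base counts span an order of magnitude between formats, so
they are log2-transformed before testing.  The run table printed for
the GB-ls-coga4 sequencing experiment ships as package data
(:func:`load_gb_ls_coga4_runs`) and drives the worked examples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from digiscaff.errors import InputDataError, ParameterError

DEFAULT_FLG_PORES_TOTAL = 250

RUN_TABLE_COLUMNS = (
    "line", "flowcell", "input_fmoles", "read_count", "bases", "n50", "file_size_gb",
)


@dataclass(frozen=True)
class FlowcellRun:
    """One sequencing run as summarized by the device report."""

    line: str
    flowcell: str  # "MIN" or "FLG"
    input_fmoles: float
    read_count: int
    bases: int
    n50: int
    file_size_gb: float
    pores: int | None = None

    def __post_init__(self):
        if self.flowcell not in ("MIN", "FLG"):
            raise InputDataError(f"flowcell must be MIN or FLG, got {self.flowcell!r}")
        for name in ("input_fmoles", "read_count", "bases", "n50", "file_size_gb"):
            if getattr(self, name) <= 0:
                raise InputDataError(f"{name} must be > 0 for run on line {self.line!r}")


@dataclass(frozen=True)
class OneSampleTResult:
    n: int
    sample_mean: float
    reference_value: float
    sd: float
    t: float
    df: int
    p_two_sided: float


@dataclass(frozen=True)
class PairedTResult:
    n_pairs: int
    mean_difference: float
    t: float
    df: int
    p_two_sided: float


@dataclass(frozen=True)
class EffectResult:
    F: float
    df_num: int
    df_den: int
    p: float


@dataclass(frozen=True)
class RmAnovaResult:
    """Univariate two-way within-subject ANOVA: main effects + interaction."""

    factor_a: EffectResult
    factor_b: EffectResult
    interaction: EffectResult


# ---------------------------------------------------------------------------
# elementary tests


def log2_values(values: Sequence[float]) -> list[float]:
    """Elementwise base-2 logarithm; rejects non-positive input."""
    out = []
    for v in values:
        if v <= 0:
            raise InputDataError(f"log2 requires positive values, got {v}")
        out.append(math.log2(v))
    return out


def one_sample_t(values: Sequence[float], reference: float) -> OneSampleTResult:
    """Two-sided one-sample t-test of ``values`` against a fixed reference.

    t = (mean - reference) / (sd / sqrt(n)) with the n-1 sample standard
    deviation.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ParameterError(f"need at least 2 values, got {arr.size}")
    sd = float(arr.std(ddof=1))
    if sd == 0:
        raise InputDataError("values have zero variance; t is undefined")
    res = stats.ttest_1samp(arr, popmean=reference)
    return OneSampleTResult(
        n=int(arr.size),
        sample_mean=float(arr.mean()),
        reference_value=float(reference),
        sd=sd,
        t=float(res.statistic),
        df=int(arr.size - 1),
        p_two_sided=float(res.pvalue),
    )


def paired_t(x: Sequence[float], y: Sequence[float]) -> PairedTResult:
    """Two-sided paired t-test: one-sample t of the differences against 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InputDataError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise ParameterError(f"need at least 2 pairs, got {x.size}")
    diffs = x - y
    if float(diffs.std(ddof=1)) == 0:
        raise InputDataError("all pairwise differences identical; t is undefined")
    res = stats.ttest_rel(x, y)
    return PairedTResult(
        n_pairs=int(x.size),
        mean_difference=float(diffs.mean()),
        t=float(res.statistic),
        df=int(x.size - 1),
        p_two_sided=float(res.pvalue),
    )


def rm_anova(data: pd.DataFrame) -> RmAnovaResult:
    """Two-way repeated-measures ANOVA (univariate, subject error strata).

    ``data`` needs columns ``subject``, ``factor_a``, ``factor_b``,
    ``value``, with every subject observed exactly once at every factor
    combination (complete balanced within-subject design).  Each effect
    is tested against its own effect-by-subject error stratum, the
    classic aov-style Error(subject/(A*B)) decomposition.
    """
    required = {"subject", "factor_a", "factor_b", "value"}
    missing = required - set(data.columns)
    if missing:
        raise InputDataError(f"missing columns: {sorted(missing)}")
    counts = data.groupby(["subject", "factor_a", "factor_b"], observed=True).size()
    if (counts != 1).any():
        raise InputDataError("design is not complete/balanced: need exactly one "
                             "observation per subject x factor_a x factor_b cell")
    n_cells = data["factor_a"].nunique() * data["factor_b"].nunique()
    per_subject = data.groupby("subject", observed=True).size()
    if (per_subject != n_cells).any():
        raise InputDataError("every subject must be observed at every factor combination")

    from statsmodels.stats.anova import AnovaRM

    fit = AnovaRM(
        data, depvar="value", subject="subject", within=["factor_a", "factor_b"]
    ).fit()
    tab = fit.anova_table

    def effect(row_name: str) -> EffectResult:
        row = tab.loc[row_name]
        return EffectResult(
            F=float(row["F Value"]),
            df_num=int(row["Num DF"]),
            df_den=int(row["Den DF"]),
            p=float(row["Pr > F"]),
        )

    return RmAnovaResult(
        factor_a=effect("factor_a"),
        factor_b=effect("factor_b"),
        interaction=effect("factor_a:factor_b"),
    )


# ---------------------------------------------------------------------------
# run tables and derived throughput metrics


def read_runs(path: str | Path) -> list[FlowcellRun]:
    """Read a delimited run table (TSV or CSV, sniffed) with columns
    line, flowcell, input_fmoles, read_count, bases, n50, file_size_gb
    and optionally pores."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = set(RUN_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise InputDataError(f"run table missing columns: {sorted(missing)}")
    runs = []
    for rec in df.to_dict("records"):
        pores = rec.get("pores")
        runs.append(
            FlowcellRun(
                line=str(rec["line"]),
                flowcell=str(rec["flowcell"]),
                input_fmoles=float(rec["input_fmoles"]),
                read_count=int(rec["read_count"]),
                bases=int(rec["bases"]),
                n50=int(rec["n50"]),
                file_size_gb=float(rec["file_size_gb"]),
                pores=None if pores is None or pd.isna(pores) else int(pores),
            )
        )
    return runs


def load_gb_ls_coga4_runs() -> list[FlowcellRun]:
    """The GB-ls-coga4 run table shipped as package data: one MinION run
    and five Flongle runs on the same D. suzukii DNA library."""
    with resources.as_file(
        resources.files("digiscaff") / "data" / "gb_ls_coga4_runs.tsv"
    ) as path:
        return read_runs(path)


def table1_summary(
    runs: Sequence[FlowcellRun],
    flg_pores_total: int = DEFAULT_FLG_PORES_TOTAL,
) -> dict[str, float]:
    """Derived throughput metrics for one line's MIN-vs-FLG comparison.

    Requires exactly one MIN run and at least one FLG run, all on the
    same line.  Percentages of a partition (MIN vs FLG shares) sum to
    100.
    """
    lines = {r.line for r in runs}
    if len(lines) != 1:
        raise InputDataError(f"expected runs from a single line, got {sorted(lines)}")
    min_runs = [r for r in runs if r.flowcell == "MIN"]
    flg_runs = [r for r in runs if r.flowcell == "FLG"]
    if len(min_runs) != 1:
        raise InputDataError(f"expected exactly one MIN reference run, got {len(min_runs)}")
    if not flg_runs:
        raise InputDataError("expected at least one FLG run")
    mref = min_runs[0]

    flg_bases = sum(r.bases for r in flg_runs)
    flg_reads = sum(r.read_count for r in flg_runs)
    flg_fmoles = sum(r.input_fmoles for r in flg_runs)
    total_bases = mref.bases + flg_bases
    total_reads = mref.read_count + flg_reads
    total_fmoles = mref.input_fmoles + flg_fmoles
    top2 = sorted(flg_runs, key=lambda r: r.bases, reverse=True)[:2]
    top2_bases = sum(r.bases for r in top2)

    return {
        "flg_total_bases": float(flg_bases),
        "flg_total_reads": float(flg_reads),
        "flg_pct_of_min_bases": 100.0 * flg_bases / mref.bases,
        "min_share_bases_pct": 100.0 * mref.bases / total_bases,
        "flg_share_bases_pct": 100.0 * flg_bases / total_bases,
        "min_share_reads_pct": 100.0 * mref.read_count / total_reads,
        "flg_share_reads_pct": 100.0 * flg_reads / total_reads,
        "mean_flg_input_fmoles": flg_fmoles / len(flg_runs),
        "min_input_fmoles": mref.input_fmoles,
        "min_fmoles_pct_of_total": 100.0 * mref.input_fmoles / total_fmoles,
        "flg_mb_per_pore": flg_bases / 1e6 / flg_pores_total,
        "top2_flg_share_of_flg_pct": 100.0 * top2_bases / flg_bases,
        "top2_flg_pct_of_min_bases": 100.0 * top2_bases / mref.bases,
    }


def flowcell_comparison_tests(runs: Sequence[FlowcellRun]) -> Mapping[str, OneSampleTResult]:
    """The standard battery of one-sample t-tests of FLG values against
    the single MIN reference: file size and N50 on the raw scale, read
    and base counts log2-transformed."""
    min_runs = [r for r in runs if r.flowcell == "MIN"]
    flg_runs = [r for r in runs if r.flowcell == "FLG"]
    if len(min_runs) != 1 or len(flg_runs) < 2:
        raise InputDataError("need one MIN run and >= 2 FLG runs")
    mref = min_runs[0]
    out = {
        "file_size_gb": one_sample_t([r.file_size_gb for r in flg_runs], mref.file_size_gb),
        "input_fmoles": one_sample_t([r.input_fmoles for r in flg_runs], mref.input_fmoles),
        "n50": one_sample_t([r.n50 for r in flg_runs], mref.n50),
        "log2_read_count": one_sample_t(
            log2_values([r.read_count for r in flg_runs]), math.log2(mref.read_count)
        ),
        "log2_bases": one_sample_t(
            log2_values([r.bases for r in flg_runs]), math.log2(mref.bases)
        ),
    }
    return out
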