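"""SNP-index mapping of a recessive mutation from phenotype-selected bulks.

The statistic is the classic bulked-segregant one: at each biallelic SNP the
SNP index of a bulk is the fraction of its reads carrying the mutant
(non-reference) allele, and

    delta(SNP index) = SNP index(mutant bulk) - SNP index(wild bulk)

At the causal locus of a recessive mutation the mutant bulk is fixed for the
mutant allele (index 1) while the wild bulk, being a phenotype-selected
mixture of 1 AA : 2 Aa, has expected index 1/3, so the expected delta peaks at
2/3 and decays with genetic distance.  Away from the causal locus both bulks
have expected index 1/2 and delta centres on 0.

Significance is assessed against a simulated null: for each of ``n_rep``
replicates the bulks are re-drawn as random Mendelian samples with no linkage
to phenotype, read counts are re-drawn at the observed depths, and the
sliding-window mean delta is recomputed; per-window quantiles of the replicate
distribution form the confidence band.  Runs of windows above the upper band
are merged into candidate intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from .simulate import BulkDesign, GenomeSpec, SITE_COLUMNS

__all__ = [
    "FilterConfig",
    "WindowConfig",
    "FilterReport",
    "ThresholdCurve",
    "CandidateInterval",
    "MappingReport",
    "snp_index",
    "delta_snp_index",
    "compute_snp_index",
    "apply_filters",
    "tile_windows",
    "sliding_windows",
    "simulate_null_thresholds",
    "call_candidates",
    "map_dataset",
]

logger = logging.getLogger(__name__)

#: Per-window table columns produced by :func:`sliding_windows`.
WINDOW_COLUMNS = ["chrom", "start", "end", "n_snps", "mean_delta"]


@dataclass(frozen=True)
class FilterConfig:
    """Site filters against sequencing/alignment artefacts.

    A site is removed when (a) one bulk has zero depth, or (b) its SNP index
    is below ``min_index`` in BOTH bulks, or (c) its alt-supporting read count
    is below ``min_support`` in BOTH bulks.
    """

    min_index: float = 0.3
    min_support: int = 7
    drop_if_missing_one_bulk: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_index <= 1.0:
            raise ValueError("min_index must be in [0, 1]")
        if self.min_support < 0:
            raise ValueError("min_support must be >= 0")


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window tiling of each chromosome."""

    window_bp: int = 2_000_000
    step_bp: int = 50_000
    min_snps_per_window: int = 3

    def __post_init__(self) -> None:
        if self.window_bp < 1 or self.step_bp < 1:
            raise ValueError("window_bp and step_bp must be positive")
        if self.step_bp > self.window_bp:
            raise ValueError("step_bp must not exceed window_bp")


@dataclass
class FilterReport:
    n_input: int = 0
    n_missing_bulk: int = 0
    n_low_index: int = 0
    n_low_support: int = 0

    @property
    def n_removed(self) -> int:
        return self.n_missing_bulk + self.n_low_index + self.n_low_support

    @property
    def n_kept(self) -> int:
        return self.n_input - self.n_removed


@dataclass
class ThresholdCurve:
    """Per-window null quantile band from the replicate simulation."""

    windows: pd.DataFrame  # chrom, start, end, n_snps (aligned with observed)
    lower: np.ndarray
    upper: np.ndarray
    n_replicates: int
    confidence: float
    seed: int


@dataclass
class CandidateInterval:
    chrom: str
    start: int
    end: int
    peak_delta: float
    peak_pos: int
    n_windows: int


@dataclass
class MappingReport:
    snp_table: pd.DataFrame
    window_table: pd.DataFrame
    thresholds: ThresholdCurve
    candidates: list[CandidateInterval]
    filter_report: FilterReport
    warnings: list[str] = field(default_factory=list)

    @property
    def funnel(self) -> dict[str, int]:
        """Stage counts: sites in, sites kept, candidate intervals out."""
        return {
            "sites_input": self.filter_report.n_input,
            "sites_kept": self.filter_report.n_kept,
            "candidate_intervals": len(self.candidates),
        }


def snp_index(ref_reads: int, alt_reads: int) -> float:
    """alt / (ref + alt); NaN when the site has no reads in this bulk."""
    if ref_reads < 0 or alt_reads < 0:
        raise ValueError("read counts must be >= 0")
    total = ref_reads + alt_reads
    return np.nan if total == 0 else alt_reads / total


def delta_snp_index(index_mut: float, index_wt: float) -> float:
    """Mutant-bulk index minus wild-bulk index; NaN if either is missing."""
    if np.isnan(index_mut) or np.isnan(index_wt):
        return np.nan
    if not (0.0 <= index_mut <= 1.0 and 0.0 <= index_wt <= 1.0):
        raise ValueError("SNP indices must lie in [0, 1]")
    return index_mut - index_wt


def compute_snp_index(sites: pd.DataFrame) -> pd.DataFrame:
    """Add ``index_mut``, ``index_wt`` and ``delta`` columns to a site table.

    Indices are NaN where the bulk's total depth is zero; delta is defined
    only when both indices are.
    """
    counts = sites[["mut_ref", "mut_alt", "wt_ref", "wt_alt"]].to_numpy()
    if (counts < 0).any():
        raise ValueError("read counts must be >= 0")
    out = sites.copy()
    mut_tot = sites["mut_ref"] + sites["mut_alt"]
    wt_tot = sites["wt_ref"] + sites["wt_alt"]
    with np.errstate(invalid="ignore", divide="ignore"):
        out["index_mut"] = np.where(mut_tot > 0, sites["mut_alt"] / mut_tot, np.nan)
        out["index_wt"] = np.where(wt_tot > 0, sites["wt_alt"] / wt_tot, np.nan)
    out["delta"] = out["index_mut"] - out["index_wt"]
    return out


def apply_filters(
    records: pd.DataFrame, cfg: FilterConfig | None = None
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop artefact-prone sites; report counts removed per rule.

    Removal rules are OR-combined; a site tripping several is attributed to
    the first in the order: missing bulk, low index in both, low support in
    both.
    """
    cfg = cfg or FilterConfig()
    rep = FilterReport(n_input=len(records))
    missing = (
        records["index_mut"].isna() | records["index_wt"].isna()
        if cfg.drop_if_missing_one_bulk
        else pd.Series(False, index=records.index)
    )
    low_index = (records["index_mut"] < cfg.min_index) & (
        records["index_wt"] < cfg.min_index
    )
    low_support = (records["mut_alt"] < cfg.min_support) & (
        records["wt_alt"] < cfg.min_support
    )
    rep.n_missing_bulk = int(missing.sum())
    rep.n_low_index = int((low_index & ~missing).sum())
    rep.n_low_support = int((low_support & ~missing & ~low_index).sum())
    kept = records[~(missing | low_index | low_support)].reset_index(drop=True)
    return kept, rep


def tile_windows(genome: GenomeSpec, cfg: WindowConfig) -> pd.DataFrame:
    """Window coordinates (1-based inclusive) tiling each chromosome.

    Starts run 1, 1+step, ... while a full window fits; a final clipped-start
    window is appended so the chromosome end is always covered.  A chromosome
    shorter than the window yields a single whole-chromosome window.
    """
    rows = []
    for c in genome.chromosomes:
        if cfg.window_bp >= c.length_bp:
            starts = np.array([1])
        else:
            starts = np.arange(1, c.length_bp - cfg.window_bp + 2, cfg.step_bp)
            last_end = starts[-1] + cfg.window_bp - 1
            if last_end < c.length_bp:
                starts = np.append(starts, c.length_bp - cfg.window_bp + 1)
        ends = np.minimum(starts + cfg.window_bp - 1, c.length_bp)
        rows.append(pd.DataFrame({"chrom": c.name, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


def _window_stats(
    windows: pd.DataFrame,
    sites: pd.DataFrame,
    delta: np.ndarray,
    min_snps: int,
) -> tuple[np.ndarray, np.ndarray]:
    """(n_snps, mean_delta) per window via prefix sums over sorted positions."""
    n_w = len(windows)
    n_snps = np.zeros(n_w, dtype=np.int64)
    mean_delta = np.full(n_w, np.nan)
    for chrom, widx in windows.groupby("chrom", sort=False).groups.items():
        smask = (sites["chrom"] == chrom).to_numpy()
        pos = sites.loc[smask, "pos"].to_numpy()
        d = delta[smask]
        order = np.argsort(pos, kind="stable")
        pos, d = pos[order], d[order]
        csum = np.concatenate([[0.0], np.cumsum(d)])
        widx = np.asarray(widx)
        lo = np.searchsorted(pos, windows.loc[widx, "start"].to_numpy(), "left")
        hi = np.searchsorted(pos, windows.loc[widx, "end"].to_numpy(), "right")
        cnt = hi - lo
        n_snps[widx] = cnt
        ok = cnt >= max(min_snps, 1)
        with np.errstate(invalid="ignore"):
            mean_delta[widx[ok]] = (csum[hi[ok]] - csum[lo[ok]]) / cnt[ok]
    return n_snps, mean_delta


def sliding_windows(
    records: pd.DataFrame, genome: GenomeSpec, cfg: WindowConfig | None = None
) -> pd.DataFrame:
    """Sliding-window arithmetic mean of delta(SNP index).

    Windows with fewer than ``min_snps_per_window`` SNPs have missing
    ``mean_delta``.  A SNP inside several overlapping windows contributes to
    each of them.
    """
    cfg = cfg or WindowConfig()
    windows = tile_windows(genome, cfg)
    n_snps, mean_delta = _window_stats(
        windows, records, records["delta"].to_numpy(dtype=float),
        cfg.min_snps_per_window,
    )
    windows["n_snps"] = n_snps
    windows["mean_delta"] = np.where(
        n_snps >= cfg.min_snps_per_window, mean_delta, np.nan
    )
    return windows[WINDOW_COLUMNS]


def null_replicate_deltas(
    records: pd.DataFrame,
    bulk_design: BulkDesign,
    n_rep: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_rep, n_sites) delta values under the no-linkage null.

    Per replicate and site, each bulk's mutant-allele count over 2n gametes is
    Binomial(2n, 1/2) — equivalent to drawing n genotypes from the Mendelian
    1/4 : 1/2 : 1/4 — and alt reads are Binomial(observed depth, bulk
    frequency).  Sites are independent across the genome, as across replicates.
    """
    m = len(records)
    depth_mut = (records["mut_ref"] + records["mut_alt"]).to_numpy()
    depth_wt = (records["wt_ref"] + records["wt_alt"]).to_numpy()
    deltas = np.empty((n_rep, m))
    for i, (n_bulk, depth) in enumerate(
        [(bulk_design.n_mutant_bulk, depth_mut), (bulk_design.n_wild_bulk, depth_wt)]
    ):
        freq = rng.binomial(2 * n_bulk, 0.5, size=(n_rep, m)) / (2 * n_bulk)
        alt = rng.binomial(np.broadcast_to(depth, (n_rep, m)), freq)
        with np.errstate(invalid="ignore", divide="ignore"):
            index = np.where(depth > 0, alt / depth, np.nan)
        if i == 0:
            deltas = index
        else:
            deltas = deltas - index
    return deltas


def simulate_null_thresholds(
    records: pd.DataFrame,
    bulk_design: BulkDesign | None = None,
    cfg: WindowConfig | None = None,
    genome: GenomeSpec | None = None,
    n_rep: int = 1000,
    confidence: float = 0.95,
    seed: int = 0,
) -> ThresholdCurve:
    """Replicate-simulation confidence band for the window mean delta.

    The band is two-sided at quantiles (1-confidence)/2 and (1+confidence)/2
    of the per-window replicate distribution; candidate calling uses only the
    upper bound, since the mutant bulk carries the mutant allele.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    bulk_design = bulk_design or BulkDesign()
    cfg = cfg or WindowConfig()
    if genome is None:
        raise ValueError("a GenomeSpec is required to tile windows")
    rng = np.random.default_rng(seed)
    deltas = null_replicate_deltas(records, bulk_design, n_rep, rng)
    windows = tile_windows(genome, cfg)
    n_w = len(windows)
    means = np.full((n_rep, n_w), np.nan)
    # reuse the same prefix-sum windowing per replicate, vectorised over reps
    for chrom, widx in windows.groupby("chrom", sort=False).groups.items():
        smask = (records["chrom"] == chrom).to_numpy()
        pos = records.loc[smask, "pos"].to_numpy()
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        d = deltas[:, smask][:, order]
        csum = np.concatenate(
            [np.zeros((n_rep, 1)), np.cumsum(d, axis=1)], axis=1
        )
        widx = np.asarray(widx)
        lo = np.searchsorted(pos, windows.loc[widx, "start"].to_numpy(), "left")
        hi = np.searchsorted(pos, windows.loc[widx, "end"].to_numpy(), "right")
        cnt = hi - lo
        ok = cnt >= cfg.min_snps_per_window
        with np.errstate(invalid="ignore"):
            means[:, widx[ok]] = (csum[:, hi[ok]] - csum[:, lo[ok]]) / cnt[ok]
    lo_q, hi_q = (1 - confidence) / 2, (1 + confidence) / 2
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
        lower = np.nanquantile(means, lo_q, axis=0)
        upper = np.nanquantile(means, hi_q, axis=0)
    n_snps, _ = _window_stats(windows, records, np.zeros(len(records)), 1)
    windows["n_snps"] = n_snps
    return ThresholdCurve(
        windows=windows,
        lower=lower,
        upper=upper,
        n_replicates=n_rep,
        confidence=confidence,
        seed=seed,
    )


def call_candidates(
    windows: pd.DataFrame, thresholds: ThresholdCurve
) -> list[CandidateInterval]:
    """Merge maximal runs of consecutive windows above the upper bound."""
    tw = thresholds.windows
    if len(tw) != len(windows) or not (
        (tw["chrom"].to_numpy() == windows["chrom"].to_numpy()).all()
        and (tw["start"].to_numpy() == windows["start"].to_numpy()).all()
        and (tw["end"].to_numpy() == windows["end"].to_numpy()).all()
    ):
        raise ValueError("windows and thresholds are not aligned")
    mean_delta = windows["mean_delta"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        exceeds = mean_delta > thresholds.upper  # NaN never exceeds
    out: list[CandidateInterval] = []
    for chrom, widx in windows.groupby("chrom", sort=False).groups.items():
        widx = np.asarray(widx)
        run: list[int] = []
        for j in widx:
            if exceeds[j]:
                run.append(j)
            elif run:
                out.append(_interval_from_run(windows, mean_delta, run))
                run = []
        if run:
            out.append(_interval_from_run(windows, mean_delta, run))
    return out


def _interval_from_run(
    windows: pd.DataFrame, mean_delta: np.ndarray, run: list[int]
) -> CandidateInterval:
    peak_j = run[int(np.argmax(mean_delta[run]))]
    start = int(windows.loc[run[0], "start"])
    end = int(windows.loc[run[-1], "end"])
    return CandidateInterval(
        chrom=str(windows.loc[run[0], "chrom"]),
        start=start,
        end=end,
        peak_delta=float(mean_delta[peak_j]),
        peak_pos=(int(windows.loc[peak_j, "start"]) + int(windows.loc[peak_j, "end"]))
        // 2,
        n_windows=len(run),
    )


def map_dataset(
    vcf_path: str | Path,
    genome: GenomeSpec,
    filter_cfg: FilterConfig | None = None,
    window_cfg: WindowConfig | None = None,
    bulk_design: BulkDesign | None = None,
    n_rep: int = 1000,
    confidence: float = 0.95,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> MappingReport:
    """End-to-end mapping: read counts -> index -> filter -> window -> null
    band -> candidate intervals; optionally writes the TSV tables."""
    from . import vcfio

    filter_cfg = filter_cfg or FilterConfig()
    window_cfg = window_cfg or WindowConfig()
    bulk_design = bulk_design or BulkDesign()
    sites = vcfio.read_vcf(vcf_path)
    warnings: list[str] = []
    records = compute_snp_index(sites)
    kept, freport = apply_filters(records, filter_cfg)
    logger.info(
        "sites: %d input, %d kept (%d missing-bulk, %d low-index, %d low-support)",
        freport.n_input, freport.n_kept, freport.n_missing_bulk,
        freport.n_low_index, freport.n_low_support,
    )
    windows = sliding_windows(kept, genome, window_cfg)
    thresholds = simulate_null_thresholds(
        kept, bulk_design, window_cfg, genome,
        n_rep=n_rep, confidence=confidence, seed=seed,
    )
    candidates = call_candidates(windows, thresholds)
    if freport.n_kept == 0:
        warnings.append("no sites survived filtering; zero candidates")
        logger.warning(warnings[-1])
    window_table = windows.copy()
    window_table["lower"] = thresholds.lower
    window_table["upper"] = thresholds.upper
    with np.errstate(invalid="ignore"):
        window_table["exceeds"] = (
            window_table["mean_delta"].to_numpy(dtype=float) > thresholds.upper
        )
    report = MappingReport(
        snp_table=kept[["chrom", "pos", "index_mut", "index_wt", "delta"]],
        window_table=window_table,
        thresholds=thresholds,
        candidates=candidates,
        filter_report=freport,
        warnings=warnings,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.snp_table.to_csv(out / "snp_index.tsv", sep="\t", index=False)
        window_table.to_csv(out / "windows.tsv", sep="\t", index=False)
        pd.DataFrame([vars(c) for c in candidates]).to_csv(
            out / "candidates.tsv", sep="\t", index=False
        )
    return report
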