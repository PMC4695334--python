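"""Synthetic two-condition dataset generator with planted ground truth.

The generator emulates the data structure of a two-condition (A vs B)
TF/epigenome study: a toy genome with non-overlapping genes; per-condition
TF peak files in which *shared* binding events are written at identical
coordinates up to a bounded jitter and *unique* events appear in only one
condition's gene-proximal window; per-factor window count tables drawn
from negative binomials whose means encode planted high/low chromatin
states; and a replicated expression matrix with planted treated-vs-control
log2 fold changes switching on at a per-gene onset time.

Every planted label — responsive class per time point, binding mode,
occupancy category, per-factor chromatin state, TSS methylation state,
context label (assisted / directed / smad3_only / unexplained) — is
recorded in a TruthTable the pipeline is expected to recover.  The layers
are generated consistently: e.g. an epigenome-directed gene carries
identical TF peaks in both conditions plus a methylation difference, and
its TF window-count state is equal in both conditions.

Each output family draws from its own RNG stream (numpy PCG64 seeded with
``[seed, stream-id]``), so adding a factor never perturbs the draws of
another family.  The same seed reproduces byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genome import GeneModel, GenomeLayout, derive_windows
from .io import (CountTable, ExpressionMatrix, PeakRecord, SampleAnnotation,
                 TIME_POINTS, write_chrom_sizes, write_counts, write_expression,
                 write_gene_table, write_peaks)
from .chromatin import ALL_FACTORS, OPEN_MARKS, TF_FACTOR
from .expression import ContextGeneSets
from .chromatin import EpigenomeGeneSets

# named RNG streams, one per output family
_STREAMS = {"layout": 0, "classes": 1, "modes": 2, "peaks": 3, "expression": 4,
            "errors": 5, "states": 6, "smad3": 10, "h3k4me3": 11, "h3k27ac": 12,
            "polii": 13, "h3k27me3": 14, "methylation": 15}


class SimulationError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    """All dials of the generator; defaults are the study conditions."""

    seed: int = 42
    n_genes: int = 1000
    n_chromosomes: int = 4
    gene_length_min: int = 2000
    gene_length_max: int = 8000
    intergenic_gap: int = 8000

    # responsive-gene classes
    frac_a_unique: float = 0.15
    frac_b_unique: float = 0.15
    frac_shared: float = 0.10
    onset_probs: dict = field(default_factory=lambda: {1: 0.10, 3: 0.20, 6: 0.30, 24: 0.40})
    persistent_response: bool = True  # responsive from onset onward vs at onset only

    # expression
    log2fc: float = 2.0
    sigma: float = 0.5
    n_replicates: int = 3
    baseline_min: float = 5.0
    baseline_max: float = 10.0
    frac_up: float = 0.7

    # binding modes
    mode_assignment: str = "by_label"  # or "by_timing"
    background_mode_probs: dict = field(default_factory=lambda: {1: 0.20, 2: 0.20, 3: 0.35, 4: 0.25})
    mode3_category_probs: dict = field(
        default_factory=lambda: {"identical": 0.5, "mixed": 0.3, "mutually_exclusive": 0.2})
    early_context_mode3: float = 0.85   # by_timing: P(mode 3) for onset <= 6 context genes
    late_context_unique: float = 0.70   # by_timing: P(own-unique mode) for onset-24 context genes
    late_context_mode3: float = 0.20

    # context labels
    frac_assisted: float = 0.30
    frac_directed: float = 0.50
    frac_smad3_only: float = 0.00
    directed_identical: float = 0.7
    assisted_hypometh: float = 0.5
    directed_open: float = 0.7
    directed_hypometh: float = 0.6
    open_mark_prob: float = 0.6  # per-mark P(differential) once open chromatin is differential

    # peaks
    peak_width_mean: float = 300.0
    peak_width_sd: float = 50.0
    min_peak_width: int = 150
    shared_jitter: int = 50
    fp_rate: float = 0.01
    fn_rate: float = 0.01

    # window counts
    nb_mean_high: float = 200.0
    nb_mean_low: float = 50.0
    nb_dispersion: float = 0.01  # 0 -> deterministic counts at the mean
    library_size: int = 1_000_000
    count_replicates: int = 1

    def validate(self) -> None:
        fr = self.frac_a_unique + self.frac_b_unique + self.frac_shared
        if not 0 <= fr <= 1:
            raise ValueError("class fractions must sum to at most 1")
        lf = self.frac_assisted + self.frac_directed + self.frac_smad3_only
        if not 0 <= lf <= 1:
            raise ValueError("context-label fractions must sum to at most 1")
        if abs(sum(self.onset_probs.values()) - 1) > 1e-9:
            raise ValueError("onset probabilities must sum to 1")
        if set(self.onset_probs) - set(TIME_POINTS):
            raise ValueError(f"onset times must be among {TIME_POINTS}")
        if self.mode_assignment not in ("by_label", "by_timing"):
            raise ValueError(f"unknown mode_assignment {self.mode_assignment!r}")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 expression replicates")


def _rng(cfg: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, _STREAMS[stream]])


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    layout: GenomeLayout
    genes: list[GeneModel]
    truth: pd.DataFrame
    peaks: dict  # (factor, condition) -> list[PeakRecord]
    counts: dict  # factor -> CountTable
    expression: ExpressionMatrix

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        (outdir / "peaks").mkdir(parents=True, exist_ok=True)
        (outdir / "counts").mkdir(exist_ok=True)
        write_chrom_sizes(self.layout, outdir / "genome.chrom.sizes")
        genes = pd.DataFrame({
            "chrom": [g.chrom for g in self.genes], "start": [g.start for g in self.genes],
            "end": [g.end for g in self.genes], "gene_id": [g.gene_id for g in self.genes],
            "score": 0, "strand": [g.strand for g in self.genes]})
        genes.to_csv(outdir / "genes.bed", sep="\t", index=False, header=False)
        write_gene_table(self.truth, outdir / "truth.tsv")
        for (factor, cond), records in self.peaks.items():
            dialect = "narrowPeak" if factor == TF_FACTOR else "broadPeak"
            ext = "narrowPeak" if factor == TF_FACTOR else "broadPeak"
            write_peaks(records, outdir / "peaks" / f"{factor}_{cond}.{ext}", dialect)
        for factor, table in self.counts.items():
            write_counts(table, outdir / "counts" / f"{factor}_counts.tsv",
                         outdir / "counts" / f"{factor}_libsizes.tsv")
        write_expression(self.expression, outdir / "expression.tsv")
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(asdict(self.config), fh, sort_keys=True)


def _choice(rng: np.random.Generator, probs: dict):
    keys = list(probs)
    p = np.array([probs[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def _simulate_layout(cfg: SimulationConfig, rng: np.random.Generator):
    """Non-overlapping genes laid left to right, round-robin over chromosomes."""
    per_chrom = [[] for _ in range(cfg.n_chromosomes)]
    for i in range(cfg.n_genes):
        per_chrom[i % cfg.n_chromosomes].append(i)
    genes: list[GeneModel | None] = [None] * cfg.n_genes
    lengths = {}
    for c, idxs in enumerate(per_chrom):
        chrom = f"chr{c + 1}"
        pos = cfg.intergenic_gap
        for i in idxs:
            glen = int(rng.integers(cfg.gene_length_min, cfg.gene_length_max + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            genes[i] = GeneModel(f"g{i:04d}", chrom, pos, pos + glen, strand)
            pos += glen + cfg.intergenic_gap
        lengths[chrom] = pos
    return GenomeLayout(lengths), [g for g in genes if g is not None]


def _assign_classes(cfg: SimulationConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    n = cfg.n_genes
    n_a = int(round(cfg.frac_a_unique * n))
    n_b = int(round(cfg.frac_b_unique * n))
    n_sh = int(round(cfg.frac_shared * n))
    classes = np.array(["A_unique"] * n_a + ["B_unique"] * n_b + ["shared"] * n_sh
                       + ["independent"] * (n - n_a - n_b - n_sh))
    rng.shuffle(classes)
    onset = np.zeros(n, dtype=int)
    responsive = classes != "independent"
    times = list(cfg.onset_probs)
    p = np.array([cfg.onset_probs[t] for t in times], dtype=float)
    onset[responsive] = rng.choice(times, size=int(responsive.sum()), p=p / p.sum())
    return classes, onset


def _own_unique_mode(cls: str) -> int:
    return 1 if cls == "A_unique" else 2


def _assign_modes_and_labels(cfg: SimulationConfig, classes, onset, rng: np.random.Generator):
    n = cfg.n_genes
    modes = np.zeros(n, dtype=int)
    categories = np.empty(n, dtype=object)
    labels = np.array([""] * n, dtype=object)

    def background_mode(i: int) -> None:
        modes[i] = _choice(rng, cfg.background_mode_probs)
        categories[i] = ({1: "A_only", 2: "B_only", 4: "unbound"}.get(modes[i])
                         or _choice(rng, cfg.mode3_category_probs))

    def mode3_category() -> str:
        return "identical" if rng.random() < cfg.directed_identical else "mixed"

    label_probs = {"epigenome_assisted": cfg.frac_assisted,
                   "epigenome_directed": cfg.frac_directed,
                   "smad3_only": cfg.frac_smad3_only,
                   "unexplained": 1 - cfg.frac_assisted - cfg.frac_directed - cfg.frac_smad3_only}
    for i in range(n):
        cls = classes[i]
        if cls in ("shared", "independent"):
            background_mode(i)
            continue
        if cfg.mode_assignment == "by_timing":
            if onset[i] <= 6:
                if rng.random() < cfg.early_context_mode3:
                    modes[i], categories[i] = 3, mode3_category()
                else:
                    modes[i], categories[i] = 4, "unbound"
            else:
                u = rng.random()
                if u < cfg.late_context_unique:
                    modes[i] = _own_unique_mode(cls)
                    categories[i] = "A_only" if modes[i] == 1 else "B_only"
                elif u < cfg.late_context_unique + cfg.late_context_mode3:
                    modes[i], categories[i] = 3, mode3_category()
                else:
                    modes[i], categories[i] = 4, "unbound"
            continue
        label = _choice(rng, label_probs)
        labels[i] = label
        if label in ("epigenome_assisted", "smad3_only"):
            modes[i] = _own_unique_mode(cls)
            categories[i] = "A_only" if modes[i] == 1 else "B_only"
        elif label == "epigenome_directed":
            modes[i], categories[i] = 3, mode3_category()
        else:  # unexplained: equivalent binding in both conditions or none
            if rng.random() < 0.5:
                modes[i], categories[i] = 3, "identical"
            else:
                modes[i], categories[i] = 4, "unbound"
    return modes, categories, labels


def _assign_chromatin_states(cfg: SimulationConfig, classes, modes, labels, rng: np.random.Generator):
    """Per-gene, per-condition high/low states for marks and methylation.

    TF state follows planted binding presence.  Context genes with an
    assisted/directed label get permissive differences in their own
    condition; all other genes get condition-equal states.
    """
    n = cfg.n_genes
    states: dict[str, np.ndarray] = {}
    for factor in ALL_FACTORS:
        states[f"{factor}_A"] = np.empty(n, dtype=object)
        states[f"{factor}_B"] = np.empty(n, dtype=object)
    for i in range(n):
        present_a = modes[i] in (1, 3)
        present_b = modes[i] in (2, 3)
        states["smad3_A"][i] = "high" if present_a else "low"
        states["smad3_B"][i] = "high" if present_b else "low"
        own = "A" if classes[i] == "A_unique" else "B"
        other = "B" if own == "A" else "A"
        label = labels[i]

        open_diff = False
        hypo_diff = False
        if label == "epigenome_assisted":
            open_diff = True
            hypo_diff = rng.random() < cfg.assisted_hypometh
        elif label == "epigenome_directed":
            open_diff = rng.random() < cfg.directed_open
            hypo_diff = rng.random() < cfg.directed_hypometh
            if not (open_diff or hypo_diff):
                hypo_diff = True

        if open_diff:
            marks = [m for m in OPEN_MARKS if rng.random() < cfg.open_mark_prob]
            if not marks:
                marks = [OPEN_MARKS[int(rng.integers(len(OPEN_MARKS)))]]
        else:
            marks = []
        for mark in OPEN_MARKS:
            if mark in marks:
                states[f"{mark}_{own}"][i] = "high"
                states[f"{mark}_{other}"][i] = "low"
            else:
                both = "high" if rng.random() < 0.5 else "low"
                states[f"{mark}_A"][i] = both
                states[f"{mark}_B"][i] = both

        if hypo_diff:
            states[f"methylation_{own}"][i] = "low"
            states[f"methylation_{other}"][i] = "high"
        else:
            both = "low" if rng.random() < 0.8 else "high"
            states["methylation_A"][i] = both
            states["methylation_B"][i] = both

        # repressive histone mark: occasional difference for context genes,
        # equal otherwise; does not feed the three set families
        if label in ("epigenome_assisted", "epigenome_directed") and rng.random() < 0.3:
            states[f"h3k27me3_{own}"][i] = "low"
            states[f"h3k27me3_{other}"][i] = "high"
        else:
            both = "low" if rng.random() < 0.7 else "high"
            states["h3k27me3_A"][i] = both
            states["h3k27me3_B"][i] = both
    return states


def _draw_width(cfg: SimulationConfig, rng: np.random.Generator) -> int:
    return max(cfg.min_peak_width, int(round(rng.normal(cfg.peak_width_mean, cfg.peak_width_sd))))


def _simulate_tf_peaks(cfg: SimulationConfig, genes, windows, modes, categories,
                       rng: np.random.Generator, rng_err: np.random.Generator):
    """Place planted binding events inside each gene-proximal window.

    Events are laid out in equal bins of the window so they cannot overlap;
    a window too small for its events raises ``SimulationError`` naming the
    gene.  Shared events are written in both conditions at the same
    coordinates, the B copy shifted by a uniform jitter within
    ±``shared_jitter``.  False positives add a spurious peak in one
    condition; false negatives drop a written peak.
    """
    peaks_a: list[PeakRecord] = []
    peaks_b: list[PeakRecord] = []
    for gi, gene in enumerate(genes):
        w = windows[gene.gene_id]
        events: list[str] = []
        mode, cat = modes[gi], categories[gi]
        if mode == 1:
            events = ["unique_A"] * (1 + int(rng.random() < 0.4))
        elif mode == 2:
            events = ["unique_B"] * (1 + int(rng.random() < 0.4))
        elif mode == 3:
            if cat == "identical":
                events = ["shared"] * (1 + int(rng.random() < 0.4))
            elif cat == "mixed":
                events = ["shared", "unique_A" if rng.random() < 0.5 else "unique_B"]
            else:  # mutually_exclusive
                events = ["unique_A", "unique_B"]
        if not events:
            continue
        width_budget = int(cfg.peak_width_mean + 4 * cfg.peak_width_sd) + 2 * cfg.shared_jitter + 10
        nbins = len(events)
        bin_width = (w.end - w.start) // nbins
        if bin_width < width_budget:
            raise SimulationError(
                f"gene {gene.gene_id}: window of {w.end - w.start} bp too small for {nbins} peak(s)")
        order = rng.permutation(nbins)
        for k, ev in enumerate(events):
            bin_start = w.start + int(order[k]) * bin_width
            width = _draw_width(cfg, rng)
            lo = bin_start + cfg.shared_jitter
            hi = bin_start + bin_width - width - cfg.shared_jitter
            pos = int(rng.integers(lo, hi + 1))
            name = f"{gene.gene_id}_e{k}"
            if ev in ("shared", "unique_A"):
                peaks_a.append(PeakRecord(gene.chrom, pos, pos + width, f"A_{name}",
                                          1.0, ".", width // 2))
            if ev == "shared":
                delta = int(rng.integers(-cfg.shared_jitter, cfg.shared_jitter + 1)) if cfg.shared_jitter else 0
                peaks_b.append(PeakRecord(gene.chrom, pos + delta, pos + delta + width,
                                          f"B_{name}", 1.0, ".", width // 2))
            elif ev == "unique_B":
                peaks_b.append(PeakRecord(gene.chrom, pos, pos + width, f"B_{name}",
                                          1.0, ".", width // 2))
    # false positives / negatives
    if cfg.fn_rate > 0:
        peaks_a = [p for p in peaks_a if rng_err.random() >= cfg.fn_rate]
        peaks_b = [p for p in peaks_b if rng_err.random() >= cfg.fn_rate]
    if cfg.fp_rate > 0:
        occupied: dict[str, list[tuple[int, int]]] = {}
        for p in peaks_a + peaks_b:
            occupied.setdefault(p.chrom, []).append((p.start, p.end))
        for gene in genes:
            w = windows[gene.gene_id]
            for cond, out in (("A", peaks_a), ("B", peaks_b)):
                if rng_err.random() >= cfg.fp_rate:
                    continue
                width = _draw_width(cfg, rng_err)
                pad = cfg.shared_jitter + 10
                for _ in range(30):
                    pos = int(rng_err.integers(w.start, max(w.start + 1, w.end - width)))
                    clash = any(pos - pad < e and pos + width + pad > s
                                for s, e in occupied.get(gene.chrom, []))
                    if not clash:
                        rec = PeakRecord(gene.chrom, pos, pos + width,
                                         f"{cond}_{gene.gene_id}_fp", 1.0, ".", width // 2)
                        out.append(rec)
                        occupied.setdefault(gene.chrom, []).append((pos, pos + width))
                        break
    key = lambda p: (p.chrom, p.start, p.name)
    return sorted(peaks_a, key=key), sorted(peaks_b, key=key)


def _mark_peaks(cfg: SimulationConfig, genes, windows, states, factor: str):
    """Broad peaks covering the window of every high-state gene (emitted for
    format completeness; downstream analysis uses the count tables)."""
    out = {"A": [], "B": []}
    for cond in ("A", "B"):
        for gi, gene in enumerate(genes):
            if states[f"{factor}_{cond}"][gi] == "high":
                w = windows[gene.gene_id]
                out[cond].append(PeakRecord(gene.chrom, w.start, w.end,
                                            f"{cond}_{factor}_{gene.gene_id}", 1.0, "."))
    return out


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    if dispersion <= 0:
        return np.full(size, int(round(mean)), dtype=int)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


def _simulate_counts(cfg: SimulationConfig, gene_ids, states, factor: str) -> CountTable:
    rng = _rng(cfg, factor)
    cols = {}
    libs = {}
    for cond in ("A", "B"):
        means = np.where(np.asarray(states[f"{factor}_{cond}"]) == "high",
                         cfg.nb_mean_high, cfg.nb_mean_low)
        for rep in range(1, cfg.count_replicates + 1):
            name = f"{cond}.{factor}.{rep}"
            draws = np.array([_nb_draw(rng, m, cfg.nb_dispersion, 1)[0] for m in means])
            cols[name] = draws
            libs[name] = float(cfg.library_size)
    counts = pd.DataFrame(cols, index=pd.Index(gene_ids, name="window_id"))
    return CountTable(counts, pd.Series(libs))


def _simulate_expression(cfg: SimulationConfig, gene_ids, classes, onset, direction,
                         rng: np.random.Generator) -> ExpressionMatrix:
    n = cfg.n_genes
    baseline = rng.uniform(cfg.baseline_min, cfg.baseline_max, size=n)
    samples: list[SampleAnnotation] = []
    columns: dict[str, np.ndarray] = {}
    for cond in ("A", "B"):
        resp_here = (classes == f"{cond}_unique") | (classes == "shared")
        for treatment in ("control", "treated"):
            for time in TIME_POINTS:
                if cfg.persistent_response:
                    active = resp_here & (onset > 0) & (onset <= time)
                else:
                    active = resp_here & (onset == time)
                mean = baseline.copy()
                if treatment == "treated":
                    mean = mean + np.where(active, direction * cfg.log2fc, 0.0)
                for rep in range(1, cfg.n_replicates + 1):
                    ann = SampleAnnotation(cond, treatment, time, rep)
                    noise = rng.normal(0.0, cfg.sigma, size=n) if cfg.sigma > 0 else 0.0
                    columns[ann.token] = mean + noise
                    samples.append(ann)
    frame = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))
    return ExpressionMatrix(frame, samples)


def simulate(cfg: SimulationConfig) -> SimulatedDataset:
    """Generate a complete dataset plus its TruthTable, deterministically."""
    cfg.validate()
    layout, genes = _simulate_layout(cfg, _rng(cfg, "layout"))
    gene_ids = [g.gene_id for g in genes]
    gp_windows = derive_windows(genes, layout, "gene_proximal")

    rng_cls = _rng(cfg, "classes")
    classes, onset = _assign_classes(cfg, rng_cls)
    direction = np.where(rng_cls.random(cfg.n_genes) < cfg.frac_up, 1.0, -1.0)
    modes, categories, labels = _assign_modes_and_labels(cfg, classes, onset, _rng(cfg, "modes"))
    states = _assign_chromatin_states(cfg, classes, modes, labels, _rng(cfg, "states"))

    peaks_a, peaks_b = _simulate_tf_peaks(cfg, genes, gp_windows, modes, categories,
                                          _rng(cfg, "peaks"), _rng(cfg, "errors"))
    peaks = {(TF_FACTOR, "A"): peaks_a, (TF_FACTOR, "B"): peaks_b}
    tss_windows = derive_windows(genes, layout, "tss_proximal")
    for mark in OPEN_MARKS + ("h3k27me3",):
        by_cond = _mark_peaks(cfg, genes, gp_windows, states, mark)
        peaks[(mark, "A")], peaks[(mark, "B")] = by_cond["A"], by_cond["B"]
    meth = _mark_peaks(cfg, genes, tss_windows, states, "methylation")
    peaks[("methylation", "A")], peaks[("methylation", "B")] = meth["A"], meth["B"]

    counts = {factor: _simulate_counts(cfg, gene_ids, states, factor) for factor in ALL_FACTORS}
    expression = _simulate_expression(cfg, gene_ids, classes, onset, direction, _rng(cfg, "expression"))

    truth = pd.DataFrame({"gene_id": gene_ids, "class": classes, "onset": onset,
                          "direction": np.where(onset > 0, np.where(direction > 0, "up", "down"), ""),
                          "mode": modes, "category": categories, "context_label": labels})
    for time in TIME_POINTS:
        for cond in ("A", "B"):
            resp_here = (classes == f"{cond}_unique") | (classes == "shared")
            if cfg.persistent_response:
                active = resp_here & (onset > 0) & (onset <= time)
            else:
                active = resp_here & (onset == time)
            truth[f"responsive_{cond}_{time}"] = active
    for factor in ALL_FACTORS:
        truth[f"{factor}_A"] = states[f"{factor}_A"]
        truth[f"{factor}_B"] = states[f"{factor}_B"]
    return SimulatedDataset(cfg, layout, genes, truth, peaks, counts, expression)


# ---------------------------------------------------------------------------
# truth accessors and truth-vs-result reporting


def truth_class_at(truth: pd.DataFrame, time: int) -> pd.Series:
    """The planted four-way context class of every gene at one time point."""
    a = truth[f"responsive_A_{time}"].to_numpy()
    b = truth[f"responsive_B_{time}"].to_numpy()
    cls = np.where(a & b, "shared", np.where(a, "A_unique", np.where(b, "B_unique", "independent")))
    return pd.Series(cls, index=truth["gene_id"].to_numpy(), name=f"class_{time}")


def truth_context_sets(truth: pd.DataFrame) -> ContextGeneSets:
    universe = set(truth["gene_id"])
    sets = ContextGeneSets(universe, "A", "B")
    ever: set[str] = set()
    for time in TIME_POINTS:
        cls = truth_class_at(truth, time)
        sets.per_time[time] = {name: set(cls.index[cls == name]) for name in
                               ("A_unique", "B_unique", "shared", "independent")}
        ever |= universe - sets.per_time[time]["independent"]
    sets.background = universe - ever
    return sets


def truth_epigenome_sets(truth: pd.DataFrame) -> EpigenomeGeneSets:
    gid = truth["gene_id"].to_numpy()
    sets = EpigenomeGeneSets()

    def diff_set(factor: str, high_in: str) -> set[str]:
        other = "B" if high_in == "A" else "A"
        mask = (truth[f"{factor}_{high_in}"] == "high") & (truth[f"{factor}_{other}"] == "low")
        return set(gid[mask.to_numpy()])

    for cond in ("A", "B"):
        other = "B" if cond == "A" else "A"
        sets.smad3_high[cond] = diff_set("smad3", cond)
        open_high: set[str] = set()
        for mark in OPEN_MARKS:
            open_high |= diff_set(mark, cond)
        sets.open_chromatin_high[cond] = open_high
        sets.hypo_methylation[cond] = diff_set("methylation", other)
    return sets


def confusion_matrix(truth_labels: pd.Series, predicted: pd.Series) -> pd.DataFrame:
    """Square confusion matrix over the union of label values; rows are
    truth, columns predictions."""
    common = truth_labels.index.intersection(predicted.index)
    if len(common) != len(truth_labels) or len(common) != len(predicted):
        raise ValueError("truth and prediction cover different gene ids")
    t = truth_labels.loc[common].astype(str)
    p = predicted.loc[common].astype(str)
    labels = sorted(set(t) | set(p))
    mat = pd.DataFrame(0, index=labels, columns=labels)
    for tv, pv in zip(t, p):
        mat.loc[tv, pv] += 1
    return mat


def accuracy(truth_labels: pd.Series, predicted: pd.Series) -> float:
    mat = confusion_matrix(truth_labels, predicted)
    return float(np.diag(mat.to_numpy()).sum() / mat.to_numpy().sum())


def set_metrics(truth_set: set[str], predicted_set: set[str]) -> dict:
    tp = len(truth_set & predicted_set)
    sens = tp / len(truth_set) if truth_set else 1.0
    prec = tp / len(predicted_set) if predicted_set else 1.0
    return {"sensitivity": sens, "precision": prec,
            "n_truth": len(truth_set), "n_predicted": len(predicted_set)}


def truth_vs_result_report(truth: pd.DataFrame, predictions: dict[str, pd.Series]) -> dict:
    """Confusion matrices and accuracies per label family.

    ``predictions`` maps a family name to a gene-id-indexed Series; the
    truth column is chosen by family: ``mode``, ``category``,
    ``context_label`` or ``class_<time>`` (per-time-point context class).
    """
    gid = truth.set_index("gene_id")
    report = {}
    for family, pred in predictions.items():
        if family.startswith("class_"):
            time = int(family.split("_")[1])
            t = truth_class_at(truth, time)
        elif family == "context_label":
            t = gid.loc[gid["context_label"] != "", "context_label"]
            # a planted context gene the pipeline failed to classify counts
            # as a miss, not an exclusion
            pred = pred.reindex(t.index).fillna("not_called")
        else:
            t = gid[family]
        mat = confusion_matrix(t, pred)
        report[family] = {"confusion": mat,
                          "accuracy": float(np.diag(mat.to_numpy()).sum() / mat.to_numpy().sum())}
    return report
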