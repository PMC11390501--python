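"""Simulation of labeled monoclonal / polyclonal single-cell CNV cohorts.

Each sample draws a cell count N ~ U[200, 2000] and a clone count
C ~ U[5, 20].  A truncal ancestor carries shared CNV events (contiguous
gene segments set to a non-neutral state); descendant clones inherit all
ancestral events and add private ones, later events overwriting earlier on
overlap (leaf-most wins).

Monoclonal samples place C leaf clones under the root with target sizes
drawn from B(N, 0.9) for one dominant clone and B(N, 0.1/(C-1)) for each
rare clone; the dominant clone is the swept truncal genotype itself.
Polyclonal samples build a deeper tree: C clades under the root (each with
full-extent private events), a few sub-clades per clade carrying short
shallow events, and int(N/2) terminal subclones with subclone target sizes
drawn from B(N, 2/N), attached by Dirichlet-weighted choice so clade sizes
are uneven (a flat single-level variant is available).  Raw binomial sizes
are renormalised to sum exactly to N by one multinomial draw with
probabilities proportional to max(raw, 1), preserving expected proportions.

Noise has two parts, both of which leave every gene's gain/loss frequency
an exact function of the clone structure: a flat, per-gene balanced
background error on copy-neutral calls, and a cell-count-scaled jitter
inside deep aberrant regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Literal, Optional

import numpy as np

from cnvcomplexity.cnv_io import ContinuousCnvMatrix, DiscreteCnvMatrix, GenePosition

__all__ = [
    "SimulationConfig",
    "ClonalTruth",
    "SimulatedSample",
    "simulate_sample",
    "simulate_cohort",
    "emit_continuous",
    "gene_positions_for",
]

NEUTRAL = 3
#: Clade-level events set two-copy losses/gains (states 1 and 5) or
#: amplifications (state 6); recent sub-clade/terminal events are shallow
#: single-copy changes (states 2 and 4).  The event-region jitter only
#: touches the deep states, which single steps cannot flip across neutral,
#: so gene-level gain/loss frequencies always stay exact clone-size ratios
#: regardless of the noise level.  Each sample draws its own amplification
#: propensity, so cohorts span a range of CNV amplitudes.
BASE_EVENT_STATES = (1, 5)
AMPLIFIED_STATE = 6
SHALLOW_EVENT_STATES = (2, 4)
DEEP_STATES = (1, 5, 6)
STATE_MULTIPLIER = np.array([np.nan, 0.0, 0.5, 1.0, 1.5, 2.0, 3.0])


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the cohort generator; defaults follow the cohort design."""

    n_min: int = 200
    n_max: int = 2000
    c_min: int = 5
    c_max: int = 20
    p_dominant: float = 0.9
    genome_size: int = 2000
    n_chromosomes: int = 22
    truncal_events_min: int = 3
    truncal_events_max: int = 8
    private_events_min: int = 1
    private_events_max: int = 5
    segment_genes_min: int = 20
    segment_genes_max: int = 200
    noise_rate: float = 0.0
    event_noise_rate: float = 0.0
    shuffle_rate: float = 0.0
    noise_ref_cells: Optional[int] = None
    deep_event_prob_max: float = 0.25
    private_scale_min: float = 1.0
    private_scale_max: float = 1.0
    subclades_min: int = 6
    subclades_max: int = 10
    dominant_clade_prob: float = 0.45
    dominant_clade_min: float = 0.80
    dominant_clade_max: float = 0.92
    subclade_events_min: int = 2
    subclade_events_max: int = 4
    subclade_genes_min: int = 8
    subclade_genes_max: int = 24
    attachment_alpha: Optional[float] = 0.5
    attachment_alpha_max: Optional[float] = 1.0
    flat_polyclonal: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.p_dominant < 1:
            raise ValueError("p_dominant must lie in (0, 1)")
        if self.n_min < 1 or self.n_max < self.n_min:
            raise ValueError("invalid cell-count range")
        if self.c_min < 2 or self.c_max < self.c_min:
            raise ValueError("invalid clone-count range")
        for lo, hi, what in (
            (self.truncal_events_min, self.truncal_events_max, "truncal event"),
            (self.private_events_min, self.private_events_max, "private event"),
            (self.segment_genes_min, self.segment_genes_max, "segment length"),
            (self.subclades_min, self.subclades_max, "sub-clade count"),
            (self.subclade_events_min, self.subclade_events_max, "sub-clade event"),
            (self.subclade_genes_min, self.subclade_genes_max, "sub-clade segment"),
        ):
            if lo < 1 or hi < lo:
                raise ValueError(f"invalid {what} range [{lo}, {hi}]")
        if self.genome_size < self.segment_genes_max:
            raise ValueError("genome smaller than the maximum segment length")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError("noise_rate must lie in [0, 1]")
        if not 0.0 <= self.event_noise_rate <= 1.0:
            raise ValueError("event_noise_rate must lie in [0, 1]")
        if not 0.0 <= self.shuffle_rate <= 1.0:
            raise ValueError("shuffle_rate must lie in [0, 1]")
        if self.noise_ref_cells is not None and self.noise_ref_cells < 1:
            raise ValueError("noise_ref_cells must be positive")
        if not 0.0 <= self.deep_event_prob_max <= 1.0:
            raise ValueError("deep_event_prob_max must lie in [0, 1]")
        if not 0.0 < self.private_scale_min <= self.private_scale_max <= 1.0:
            raise ValueError("private scale range must satisfy 0 < min <= max <= 1")
        if self.attachment_alpha is not None and self.attachment_alpha <= 0:
            raise ValueError("attachment_alpha must be positive (or None for uniform)")
        if self.attachment_alpha_max is not None:
            if self.attachment_alpha is None or self.attachment_alpha_max < self.attachment_alpha:
                raise ValueError("attachment_alpha_max needs attachment_alpha <= max")
        if not 0.0 <= self.dominant_clade_prob <= 1.0:
            raise ValueError("dominant_clade_prob must lie in [0, 1]")
        if not 0.0 < self.dominant_clade_min <= self.dominant_clade_max < 1.0:
            raise ValueError("dominant clade weight range must lie in (0, 1)")

    def _scaled(self, base: float, n_cells: int, cap: float) -> float:
        if self.noise_ref_cells is None:
            return base
        return min(cap, base * float(np.sqrt(self.noise_ref_cells / n_cells)))

    def effective_event_noise_rate(self, n_cells: int) -> float:
        """State-jitter probability for cells inside CNV events.

        With ``noise_ref_cells`` unset this is the flat ``event_noise_rate``;
        when set it scales as ``event_noise_rate * sqrt(noise_ref_cells /
        n_cells)`` (capped at 0.5): smaller samples get noisier calls in
        aberrant regions, mimicking how CNV inference sharpens as more cells
        are pooled.  Because events use deep states, this jitter never flips
        a call across copy-neutral and leaves gene-level gain/loss
        frequencies untouched.
        """
        return self._scaled(self.event_noise_rate, n_cells, 0.9)

    def effective_shuffle_rate(self, n_cells: int) -> float:
        """Fraction of genes whose states are shuffled across cells.

        A shuffled gene keeps its gene-level gain/loss frequency exactly but
        loses its cell assignment, modelling per-cell call misassignment
        (balanced false positives/negatives).  Scales with cell count like
        the jitter, capped at 1.
        """
        return self._scaled(self.shuffle_rate, n_cells, 1.0)


#: Cohort defaults used by the benchmark and the CLI.  Real discrete CNV
#: calls are noisy (noiseless matrices would make within-clone cells
#: bit-identical, which no inference tool produces): a flat background
#: error floor affects copy-neutral calls, and calls inside aberrant
#: regions carry extra uncertainty that shrinks as more cells are pooled.
DEFAULT_COHORT_CONFIG = SimulationConfig(
    noise_rate=0.10,
    event_noise_rate=0.30,
    noise_ref_cells=2000,
)

Event = tuple[int, int, int]  # (start_gene, end_gene_exclusive, state)


@dataclass
class ClonalTruth:
    """Ground truth for one simulated sample."""

    label: Literal["monoclonal", "polyclonal"]
    clone_tree: dict[str, Optional[str]]  # clone -> parent (root -> None)
    clone_events: dict[str, list[Event]]  # private events per clone
    clone_sizes: dict[str, int]
    cell_assignment: dict[str, str]  # cell -> clone

    @property
    def n_cells(self) -> int:
        return len(self.cell_assignment)

    @property
    def n_clones(self) -> int:
        return len(self.clone_tree)

    def lineage(self, clone: str) -> list[str]:
        """Clones from the root down to ``clone`` (inclusive)."""
        path = [clone]
        while (parent := self.clone_tree[path[-1]]) is not None:
            path.append(parent)
        return path[::-1]

    def cumulative_events(self, clone: str) -> list[Event]:
        """All events along the root-to-clone path, ancestor first."""
        out: list[Event] = []
        for node in self.lineage(clone):
            out.extend(self.clone_events[node])
        return out


@dataclass
class SimulatedSample:
    sample_id: str
    matrix: DiscreteCnvMatrix
    truth: ClonalTruth

    def __post_init__(self) -> None:
        if self.matrix.n_cells != self.truth.n_cells:
            raise ValueError("matrix cell count disagrees with truth")


def _draw_events(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    n_events: int,
    deep_prob: float,
    length_lo: int,
    length_hi: int,
    length_scale: float = 1.0,
    shallow: bool = False,
) -> list[Event]:
    events: list[Event] = []
    for _ in range(n_events):
        length = int(rng.integers(length_lo, length_hi + 1))
        length = max(2, int(round(length * length_scale)))
        start = int(rng.integers(0, cfg.genome_size - length + 1))
        if shallow:
            state = int(rng.choice(SHALLOW_EVENT_STATES))
        elif rng.random() < deep_prob:
            state = AMPLIFIED_STATE
        else:
            state = int(rng.choice(BASE_EVENT_STATES))
        events.append((start, start + length, state))
    return events


def _normalise_sizes(rng: np.random.Generator, raw: np.ndarray, n_cells: int) -> np.ndarray:
    # One multinomial draw with probabilities ~ max(raw, 1) keeps the
    # expected proportions of the binomial design while summing exactly to
    # N.  Only zero draws are lifted to 1, so large clones are not shrunk
    # by a clone-count-dependent pseudocount.
    smoothed = np.maximum(raw, 1.0)
    return rng.multinomial(n_cells, smoothed / smoothed.sum())


def _clone_profile(base: np.ndarray, events: list[Event]) -> np.ndarray:
    profile = base.copy()
    for start, end, state in events:
        profile[start:end] = state
    return profile


def simulate_sample(
    kind: Literal["monoclonal", "polyclonal"],
    cfg: SimulationConfig = SimulationConfig(),
    rng: np.random.Generator | int | None = None,
    *,
    sample_id: str = "sample",
) -> SimulatedSample:
    """Generate one labeled sample with its discrete CNV matrix and truth."""
    if kind not in ("monoclonal", "polyclonal"):
        raise ValueError(f"kind must be 'monoclonal' or 'polyclonal', got {kind!r}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    n_cells = int(rng.integers(cfg.n_min, cfg.n_max + 1))
    n_clones = int(rng.integers(cfg.c_min, cfg.c_max + 1))
    # Per-sample latents: propensity for amplification events and the
    # genomic extent of clade-level events.  Tumors vary widely in CNV
    # amplitude and subclonal divergence while sharing the same clonal
    # architecture classes.
    deep_prob = float(rng.uniform(0.0, cfg.deep_event_prob_max))
    private_scale = float(rng.uniform(cfg.private_scale_min, cfg.private_scale_max))

    tree: dict[str, Optional[str]] = {"root": None}
    events: dict[str, list[Event]] = {
        "root": _draw_events(
            rng, cfg,
            int(rng.integers(cfg.truncal_events_min, cfg.truncal_events_max + 1)),
            deep_prob, cfg.segment_genes_min, cfg.segment_genes_max,
        )
    }

    def add_clone(name: str, parent: str, long_events: bool, n_events: int | None = None,
                  scale: float = 1.0) -> None:
        if n_events is None:
            lo, hi = (
                (cfg.private_events_min, cfg.private_events_max)
                if long_events
                else (cfg.subclade_events_min, cfg.subclade_events_max)
            )
            n_events = int(rng.integers(lo, hi + 1))
        glo, ghi = (
            (cfg.segment_genes_min, cfg.segment_genes_max)
            if long_events
            else (cfg.subclade_genes_min, cfg.subclade_genes_max)
        )
        tree[name] = parent
        events[name] = _draw_events(
            rng, cfg, n_events, deep_prob, glo, ghi, scale, shallow=not long_events
        )

    if kind == "monoclonal":
        # The dominant clone is the swept truncal genotype itself; rare
        # clones diverge from it with long private events.
        leaves = [f"clone_{i}" for i in range(n_clones)]
        add_clone(leaves[0], "root", long_events=False, n_events=0)
        for name in leaves[1:]:
            add_clone(name, "root", long_events=True)
        p_rare = (1.0 - cfg.p_dominant) / (n_clones - 1)
        raw = np.concatenate([
            [rng.binomial(n_cells, cfg.p_dominant)],
            rng.binomial(n_cells, p_rare, size=n_clones - 1),
        ]).astype(float)
        sized_clones = leaves
    else:
        n_sub = int(n_cells / 2)
        if cfg.flat_polyclonal:
            parents = ["root"] * n_sub
        else:
            # Level 1: C clades with full-extent events (scaled by the
            # per-sample divergence latent).  Level 2: each clade splits
            # into a few sub-clades carrying short, recent events -- they
            # occupy little genomic extent (negligible variance) but
            # register as distinct intermediate alteration frequencies.
            # With probability dominant_clade_prob one clade dominates the
            # sample; like the monoclonal dominant clone it is the swept
            # truncal genotype itself, diverging only through sub-clades.
            has_dominant = rng.random() < cfg.dominant_clade_prob
            inter = [f"clone_{i}" for i in range(n_clones)]
            for k, name in enumerate(inter):
                if has_dominant and k == 0:
                    add_clone(name, "root", long_events=True, n_events=0)
                else:
                    add_clone(name, "root", long_events=True, scale=private_scale)
            subclades: list[str] = []
            for i, name in enumerate(inter):
                n_sc = int(rng.integers(cfg.subclades_min, cfg.subclades_max + 1))
                for j in range(n_sc):
                    sc_name = f"clone_{i}_{j}"
                    add_clone(sc_name, name, long_events=False)
                    subclades.append(sc_name)
            if cfg.attachment_alpha is None:
                idx = rng.integers(0, len(subclades), size=n_sub)
            else:
                # Dirichlet-weighted attachment: clades and sub-clades cover
                # uneven cell fractions, spreading alteration frequencies
                # over (0, 1) instead of piling up near 1/C.  A per-sample
                # concentration (when a range is configured) varies how
                # skewed the clade sizes are from tumor to tumor.
                alpha = cfg.attachment_alpha
                if cfg.attachment_alpha_max is not None:
                    alpha = float(rng.uniform(alpha, cfg.attachment_alpha_max))
                if has_dominant:
                    # A moderately dominant clade: most cell pairs then fall
                    # inside it (which deflates dispersion-based
                    # heterogeneity scores) while its sub-clades still
                    # spread alteration frequencies.  Skewed minority
                    # weights keep a few clades at binnable (>0.05)
                    # frequencies instead of dust.
                    u = float(rng.uniform(cfg.dominant_clade_min, cfg.dominant_clade_max))
                    rest = rng.dirichlet([0.4] * (n_clones - 1)) * (1.0 - u)
                    clade_w = np.concatenate([[u], rest])
                else:
                    clade_w = rng.dirichlet([alpha] * n_clones)
                sc_per_clade = [[s for s in subclades if tree[s] == c] for c in inter]
                weights = np.concatenate([
                    clade_w[i] * rng.dirichlet([1.0] * len(group))
                    for i, group in enumerate(sc_per_clade)
                ])
                order = [s for group in sc_per_clade for s in group]
                idx = rng.choice(len(order), size=n_sub, p=weights)
                subclades = order
            parents = [subclades[i] for i in idx]
        # Terminal subclones also carry only short recent events.
        sized_clones = [f"sub_{i}" for i in range(n_sub)]
        for name, parent in zip(sized_clones, parents):
            add_clone(name, parent, long_events=False, n_events=int(rng.integers(1, 3)))
        raw = rng.binomial(n_cells, 2.0 / n_cells, size=n_sub).astype(float)

    sizes = _normalise_sizes(rng, raw, n_cells)
    clone_sizes = {name: int(s) for name, s in zip(sized_clones, sizes)}
    for name in tree:
        clone_sizes.setdefault(name, 0)

    truth = ClonalTruth(
        label=kind,
        clone_tree=tree,
        clone_events=events,
        clone_sizes=clone_sizes,
        cell_assignment={},
    )

    # Build cumulative profiles top-down so each clone reuses its parent's.
    base = np.full(cfg.genome_size, NEUTRAL, dtype=np.int8)
    profiles: dict[str, np.ndarray] = {"root": _clone_profile(base, events["root"])}

    def profile_of(clone: str) -> np.ndarray:
        if clone not in profiles:
            parent = tree[clone]
            profiles[clone] = _clone_profile(profile_of(parent), events[clone])
        return profiles[clone]

    width = len(str(n_cells))
    cell_ids: list[str] = []
    columns: list[np.ndarray] = []
    cell_no = 0
    for clone in sized_clones:
        size = clone_sizes[clone]
        if size == 0:
            continue
        prof = profile_of(clone)
        for _ in range(size):
            cell_id = f"cell_{cell_no:0{width}d}"
            cell_ids.append(cell_id)
            truth.cell_assignment[cell_id] = clone
            cell_no += 1
        columns.append(np.repeat(prof[:, None], size, axis=1))
    states = np.concatenate(columns, axis=1)

    noisy = states.astype(np.int16)

    q_event = cfg.effective_event_noise_rate(n_cells)
    if q_event > 0:
        # Jitter inside strongly aberrant regions: +/-1 on deep-state calls.
        # Single steps cannot cross copy-neutral from states {1, 5, 6}, so
        # gene-level gain/loss frequencies are exactly preserved; only the
        # cell-level profiles get noisier (more so in small samples).
        aberrant = np.isin(states, DEEP_STATES)
        jit = aberrant & (rng.random(states.shape) < q_event)
        noisy[jit] += rng.choice([-1, 1], size=int(jit.sum()))

    q = cfg.noise_rate
    if q > 0:
        # Background error floor on copy-neutral calls, balanced per gene:
        # exactly round(q*n/2) neutral cells shift up and as many shift
        # down, so every gene's background gain and loss frequencies equal
        # round(q*n/2)/n deterministically, independent of sample size.
        for g in range(cfg.genome_size):
            idx = np.nonzero(states[g] == NEUTRAL)[0]
            k = int(round(q * idx.size / 2))
            if k:
                pick = rng.choice(idx, size=2 * k, replace=False)
                noisy[g, pick[:k]] += 1
                noisy[g, pick[k:]] -= 1

    states = np.clip(noisy, 1, 6).astype(np.int8)

    beta = cfg.effective_shuffle_rate(n_cells)
    if beta > 0:
        shuffled_genes = np.nonzero(rng.random(cfg.genome_size) < beta)[0]
        for g in shuffled_genes:
            states[g] = states[g, rng.permutation(n_cells)]

    gene_ids = [f"gene_{i:04d}" for i in range(cfg.genome_size)]
    matrix = DiscreteCnvMatrix(gene_ids, cell_ids, states)
    return SimulatedSample(sample_id=sample_id, matrix=matrix, truth=truth)


def simulate_cohort(
    n_mono: int,
    n_poly: int,
    cfg: SimulationConfig = DEFAULT_COHORT_CONFIG,
    seed: int | None = None,
) -> list[SimulatedSample]:
    """Generate ``n_mono`` monoclonal then ``n_poly`` polyclonal samples.

    Deterministic for a given seed: the same call yields bit-identical
    matrices and truths.
    """
    if n_mono < 0 or n_poly < 0:
        raise ValueError("sample counts must be non-negative")
    rng = np.random.default_rng(seed)
    samples: list[SimulatedSample] = []
    for i in range(n_mono):
        samples.append(
            simulate_sample("monoclonal", cfg, rng, sample_id=f"mono_{i + 1:03d}")
        )
    for i in range(n_poly):
        samples.append(
            simulate_sample("polyclonal", cfg, rng, sample_id=f"poly_{i + 1:03d}")
        )
    return samples


def emit_continuous(
    sample: SimulatedSample,
    sigma: float,
    rng: np.random.Generator | int | None = None,
) -> ContinuousCnvMatrix:
    """Map discrete states to expression-ratio multipliers plus Gaussian noise.

    States {1..6} map to {0, 0.5, 1, 1.5, 2, 3}; independent N(0, sigma^2)
    noise is added to every entry.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    values = STATE_MULTIPLIER[sample.matrix.states]
    if sigma > 0:
        values = values + rng.normal(0.0, sigma, size=values.shape)
    return ContinuousCnvMatrix(
        list(sample.matrix.gene_ids), list(sample.matrix.cell_ids), values
    )


def gene_positions_for(cfg: SimulationConfig) -> list[GenePosition]:
    """Synthetic gene ordering table matching the simulated genome.

    Genes are spread evenly over ``n_chromosomes`` chromosomes in index
    order, 1 kb apart; purely a convenience for writing InferCNV-style
    sidecar files.
    """
    per_chrom = -(-cfg.genome_size // cfg.n_chromosomes)  # ceil
    rows = []
    for i in range(cfg.genome_size):
        chrom = f"chr{i // per_chrom + 1}"
        offset = i % per_chrom
        start = offset * 1000 + 1
        rows.append(GenePosition(f"gene_{i:04d}", chrom, start, start + 999))
    return rows
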