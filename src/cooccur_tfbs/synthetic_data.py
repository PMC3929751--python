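"""Seeded synthetic inputs with known ground truth.

The generator emulates the two kinds of input the pipeline consumes in a
real study:

* a paired two-group log2 expression matrix (matched biopsies: the same
  donor sampled in the control and the treated condition) with a chosen
  set of planted differentially expressed genes, and
* a promoter universe in which a chosen subset of genes carries an
  implanted heterotypic cluster: one consensus instance of each of three
  forkhead-like factors that share the TGTTT core but have divergent
  flanks, placed with pairwise start distances within the clustering
  window.

All randomness flows from the single seed in the config; identical
seeds give byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import BASES, CountMatrix, PromoterRecord, PromoterSet, reverse_complement

CORE = "TGTTT"
COLUMN_TOTAL = 20  # observations per matrix column


@dataclasses.dataclass
class SimulationConfig:
    """Study conditions for the synthetic benchmark.

    Defaults mirror a matched-biopsy microarray design with three donor
    pairs: a strong planted effect (2 log2 units) against small residual
    paired noise, a 2000-gene universe with 100 planted DE genes, and
    implanted three-factor promoter clusters in 70% of the DE genes.
    """

    n_genes_universe: int = 2000
    n_samples_per_group: int = 3
    n_de: int = 100
    effect: float = 2.0
    noise_sd: float = 0.05
    gc: float = 0.45
    promoter_length: int = 2000
    tss_offset: int = 1500
    cluster_span: int = 50
    cluster_fraction: float = 0.70
    seed: int = 0

    def __post_init__(self):
        for name in ("n_genes_universe", "n_samples_per_group", "n_de", "promoter_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 < self.gc < 1.0:
            raise ValueError(f"gc must be in (0, 1), got {self.gc}")
        if self.n_de > self.n_genes_universe:
            raise ValueError("n_de cannot exceed n_genes_universe")
        if not 0.0 <= self.cluster_fraction <= 1.0:
            raise ValueError("cluster_fraction must be in [0, 1]")


@dataclasses.dataclass
class SyntheticTruth:
    de_genes: set
    planted_effect: float
    cluster_genes: set
    implant_positions: dict  # gene -> list of (factor, start, strand)
    seed: int

    def to_json(self, path) -> None:
        payload = {
            "de_genes": sorted(self.de_genes),
            "planted_effect": self.planted_effect,
            "cluster_genes": sorted(self.cluster_genes),
            "implant_positions": {
                g: [[f, int(s), st] for f, s, st in v]
                for g, v in sorted(self.implant_positions.items())
            },
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            de_genes=set(d["de_genes"]),
            planted_effect=d["planted_effect"],
            cluster_genes=set(d["cluster_genes"]),
            implant_positions={
                g: [(f, int(s), st) for f, s, st in v]
                for g, v in d["implant_positions"].items()
            },
            seed=d["seed"],
        )


def gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(
    config: SimulationConfig,
    de_genes: Optional[Sequence[str]] = None,
    rng: Optional[np.random.Generator] = None,
):
    """Paired two-group log2 expression with planted DE genes.

    Per gene and donor pair a shared baseline ~ Normal(8, 1.5) is drawn;
    the wounded sample of a pair adds ``effect`` for DE genes; every
    cell gets iid Normal(0, noise_sd) measurement noise.

    Returns ``(values, design, truth)`` where ``values`` is a genes x
    samples DataFrame and ``design`` maps each sample to its group
    ("control"/"wounded") and pair id.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    genes = gene_names(config.n_genes_universe)
    n_pairs = config.n_samples_per_group
    if de_genes is None:
        de = sorted(rng.choice(genes, size=config.n_de, replace=False).tolist())
    else:
        de = sorted(de_genes)
        if not set(de) <= set(genes):
            raise ValueError("de_genes not contained in the gene universe")
    de_mask = np.isin(genes, de)

    baseline = rng.normal(8.0, 1.5, size=(len(genes), n_pairs))
    control = baseline + rng.normal(0.0, config.noise_sd, size=baseline.shape)
    wounded = baseline + rng.normal(0.0, config.noise_sd, size=baseline.shape)
    wounded[de_mask, :] += config.effect

    pair_ids = [f"P{i}" for i in range(1, n_pairs + 1)]
    columns = [f"{p}_control" for p in pair_ids] + [f"{p}_wounded" for p in pair_ids]
    values = pd.DataFrame(
        np.hstack([control, wounded]), index=genes, columns=columns
    )
    design = pd.DataFrame(
        {
            "group": ["control"] * n_pairs + ["wounded"] * n_pairs,
            "pair": pair_ids + pair_ids,
        },
        index=pd.Index(columns, name="sample"),
    )
    truth = SyntheticTruth(
        de_genes=set(de),
        planted_effect=config.effect,
        cluster_genes=set(),
        implant_positions={},
        seed=config.seed,
    )
    return values, design, truth


# ---------------------------------------------------------------------------
# motif matrices
# ---------------------------------------------------------------------------

def _dirichlet_column(
    rng: np.random.Generator, total: int = COLUMN_TOTAL, max_count: Optional[int] = None
) -> np.ndarray:
    """One motif column: counts ~ Multinomial(total, Dirichlet(0.5)).

    ``max_count`` caps the dominant base so a flank column can never be
    fully conserved; the TGTTT core block must remain strictly the most
    informative 5-column window of the matrix.
    """
    while True:
        p = rng.dirichlet(np.full(4, 0.5))
        counts = rng.multinomial(total, p)
        if max_count is None or counts.max() <= max_count:
            return counts.astype(float)


def make_foxo_like_matrices(seed: int) -> list[CountMatrix]:
    """Three forkhead-like count matrices sharing an exact TGTTT core
    block (count 20 on the consensus base, 0 elsewhere) with distinct
    Dirichlet(0.5)-drawn flanking columns and lengths between 8 and 12."""
    rng = np.random.default_rng(seed)
    core_cols = np.zeros((5, 4))
    for i, b in enumerate(CORE):
        core_cols[i, BASES.index(b)] = COLUMN_TOTAL
    matrices: list[CountMatrix] = []
    lengths = rng.integers(8, 13, size=3)
    seen_flanks: set[bytes] = set()
    for k, L in enumerate(lengths, start=1):
        while True:
            n_flank = int(L) - 5
            left = int(rng.integers(0, n_flank + 1))
            flanks = np.array(
                [_dirichlet_column(rng, max_count=COLUMN_TOTAL - 2) for _ in range(n_flank)]
            )
            key = flanks.tobytes()
            if key not in seen_flanks:
                seen_flanks.add(key)
                break
        counts = np.vstack(
            [flanks[:left], core_cols, flanks[left:]]
            if n_flank
            else [core_cols]
        )
        matrices.append(CountMatrix(f"FOXO{k}_SYN", counts))
    return matrices


def make_decoy_matrices(n: int, seed: int) -> list[CountMatrix]:
    """Decoy factors: random peaked matrices with no constructed TGTTT core."""
    rng = np.random.default_rng(seed)
    out: list[CountMatrix] = []
    for k in range(1, n + 1):
        L = int(rng.integers(8, 13))
        while True:
            counts = np.array([_dirichlet_column(rng) for _ in range(L)])
            consensus = "".join(BASES[i] for i in counts.argmax(axis=1))
            if CORE not in consensus:
                break
        out.append(CountMatrix(f"DECOY{k:02d}", counts))
    return out


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------

def _background_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.int8)


def simulate_promoters(
    config: SimulationConfig,
    factors: Sequence[CountMatrix],
    cluster_genes: Optional[Sequence[str]] = None,
    rng: Optional[np.random.Generator] = None,
):
    """Background promoters at the configured GC with consensus clusters
    implanted in ``cluster_genes``.

    Each implanted promoter receives one consensus instance of every
    factor on a random strand; instances do not overlap one another, all
    pairwise start distances are <= ``cluster_span``, and implants stay
    clear of the promoter edges.  Implanted coordinates are recorded in
    the returned truth.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    genes = gene_names(config.n_genes_universe)
    lengths = [len(m) for m in factors]
    span = config.cluster_span
    margin = 20
    need = span + max(lengths) + 2 * margin
    if need > config.promoter_length:
        raise ValueError(
            f"cluster cannot fit: span {span} + motifs needs {need} bp "
            f"but promoters are {config.promoter_length} bp"
        )
    if cluster_genes is None:
        n_cluster = int(round(config.cluster_fraction * config.n_de))
        cluster = sorted(rng.choice(genes, size=n_cluster, replace=False).tolist())
    else:
        cluster = sorted(cluster_genes)
        if not set(cluster) <= set(genes):
            raise ValueError("cluster_genes not contained in the gene universe")
    cluster_set = set(cluster)

    records: dict[str, PromoterRecord] = {}
    implant_positions: dict[str, list[tuple[str, int, str]]] = {}
    for gene in genes:
        seq_idx = _background_sequence(rng, config.promoter_length, config.gc)
        seq = "".join(BASES[i] for i in seq_idx)
        if gene in cluster_set:
            order = rng.permutation(len(factors))
            lens = [lengths[i] for i in order]
            # pairwise start distances are bounded by the first-to-last
            # start distance; keep that <= span while motifs do not overlap
            slack = span - (lens[0] + lens[1])
            if slack < 0:
                raise ValueError("cluster cannot fit: motif lengths exceed the span")
            g1 = int(rng.integers(0, slack + 1))
            g2 = int(rng.integers(0, slack - g1 + 1))
            anchor = int(
                rng.integers(margin, config.promoter_length - margin - (span + lens[2]) + 1)
            )
            starts = [anchor, anchor + lens[0] + g1, anchor + lens[0] + g1 + lens[1] + g2]
            placed: list[tuple[str, int, str]] = []
            for oi, start in zip(order, starts):
                factor = factors[oi]
                word = factor.consensus
                strand = "+" if rng.random() < 0.5 else "-"
                ins = word if strand == "+" else reverse_complement(word)
                seq = seq[:start] + ins + seq[start + len(ins):]
                placed.append((factor.factor_name, start, strand))
            implant_positions[gene] = sorted(placed, key=lambda t: t[1])
        records[gene] = PromoterRecord(seq, config.tss_offset)

    truth = SyntheticTruth(
        de_genes=set(),
        planted_effect=config.effect,
        cluster_genes=cluster_set,
        implant_positions=implant_positions,
        seed=config.seed,
    )
    return PromoterSet(records), truth


# ---------------------------------------------------------------------------
# whole-study orchestration
# ---------------------------------------------------------------------------

def simulate_study(config: SimulationConfig, n_decoys: int = 20):
    """Generate a coherent synthetic study: expression, promoters,
    implanted + decoy matrices, and a single merged truth.

    Cluster genes are a ``cluster_fraction`` subset of the planted DE
    genes so that end-to-end recovery is well-defined.
    """
    root = np.random.SeedSequence(config.seed)
    ss = root.spawn(5)
    rng_pick = np.random.default_rng(ss[0])
    genes = gene_names(config.n_genes_universe)
    de = sorted(rng_pick.choice(genes, size=config.n_de, replace=False).tolist())
    n_cluster = int(round(config.cluster_fraction * config.n_de))
    cluster = sorted(rng_pick.choice(de, size=n_cluster, replace=False).tolist())

    factors = make_foxo_like_matrices(int(ss[1].generate_state(1)[0] % 2**31))
    decoys = make_decoy_matrices(n_decoys, int(ss[2].generate_state(1)[0] % 2**31))

    values, design, truth = simulate_expression(
        config, de_genes=de, rng=np.random.default_rng(ss[3])
    )
    promoters, ptruth = simulate_promoters(
        config, factors, cluster_genes=cluster, rng=np.random.default_rng(ss[4])
    )
    truth.cluster_genes = ptruth.cluster_genes
    truth.implant_positions = ptruth.implant_positions
    return {
        "values": values,
        "design": design,
        "promoters": promoters,
        "factors": factors,
        "decoys": decoys,
        "truth": truth,
    }
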