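"""Synthetic benchmark generator with planted block structure.

Emulates the statistical shape of the curated lncRNA-disease benchmark
(78 lncRNAs, 113 diseases, 210 experimentally verified associations, a sparse
bipartite graph whose diseases cluster in the MeSH hierarchy) so that every
other module is testable without any download.

Entities are partitioned into disease/lncRNA co-modules ("blocks").  Diseases
of a block share a deep tree-number prefix, giving high within-block semantic
similarity; lncRNAs of a block associate almost exclusively with that block's
diseases; a small number of cross-block noise associations is sprinkled on
top.  A round-robin pass inside each block guarantees that every lncRNA and
every disease carries at least one association, so the generated edge list
parses back to exactly the configured entity counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data_io import AssociationDataset, write_associations, write_tree_numbers

__all__ = ["SynthConfig", "SyntheticBenchmark", "generate", "permute_labels"]


@dataclass(frozen=True)
class SynthConfig:
    """Generator configuration.

    Defaults reproduce the benchmark's shape: 78 lncRNAs x 113 diseases with
    exactly 6 * 33 + 12 = 210 associations in 6 planted blocks, tree depth 4
    (a realistic MeSH disease-descriptor depth).
    """

    n_lncrna: int = 78
    n_disease: int = 113
    n_blocks: int = 6
    tree_depth: int = 4
    assoc_per_block: int = 33
    noise_assoc: int = 12
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_blocks > min(self.n_lncrna, self.n_disease):
            raise ValueError("more blocks than lncRNAs or diseases")
        if self.n_blocks < 1:
            raise ValueError("need at least one block")
        if self.tree_depth < 2:
            raise ValueError("tree_depth must be at least 2")
        if self.assoc_per_block < 1 or self.noise_assoc < 0:
            raise ValueError("association counts must be nonnegative")

    @property
    def n_associations(self) -> int:
        return self.n_blocks * self.assoc_per_block + self.noise_assoc


@dataclass(frozen=True)
class SyntheticBenchmark:
    """Generated dataset plus its ground truth."""

    dataset: AssociationDataset
    tree_numbers: dict
    lncrna_blocks: dict  # lncrna id -> block index
    disease_blocks: dict  # disease id -> block index

    def write(self, outdir: str | Path) -> dict:
        """Write associations, tree numbers and block labels as TSV; returns
        the three paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "associations": outdir / "associations.tsv",
            "tree_numbers": outdir / "tree_numbers.tsv",
            "blocks": outdir / "blocks.tsv",
        }
        write_associations(self.dataset, paths["associations"])
        write_tree_numbers(self.tree_numbers, paths["tree_numbers"])
        lines = ["id\tkind\tblock"]
        lines += [f"{n}\tlncrna\t{b}" for n, b in self.lncrna_blocks.items()]
        lines += [f"{n}\tdisease\t{b}" for n, b in self.disease_blocks.items()]
        paths["blocks"].write_text("\n".join(lines) + "\n")
        return paths


def _split_sizes(n: int, k: int) -> list[int]:
    base, extra = divmod(n, k)
    return [base + (b < extra) for b in range(k)]


def generate(config: SynthConfig | None = None) -> SyntheticBenchmark:
    """Generate a planted-block benchmark.

    One integer seed drives the whole generation; independent substreams are
    derived per output (tree numbers, in-block associations, noise) so adding
    an output never shifts the earlier ones.
    """
    if config is None:
        config = SynthConfig()
    cells = config.n_lncrna * config.n_disease
    if config.n_associations > cells:
        raise ValueError(
            f"requested {config.n_associations} associations but the matrix "
            f"has only {cells} cells"
        )
    tree_rng, assoc_rng, noise_rng = (
        np.random.default_rng(s)
        for s in np.random.SeedSequence(config.seed).spawn(3)
    )

    lncrna_ids = [f"lnc{i + 1:03d}" for i in range(config.n_lncrna)]
    disease_ids = [f"disease{j + 1:03d}" for j in range(config.n_disease)]
    lnc_sizes = _split_sizes(config.n_lncrna, config.n_blocks)
    dis_sizes = _split_sizes(config.n_disease, config.n_blocks)
    lnc_block = np.repeat(np.arange(config.n_blocks), lnc_sizes)
    dis_block = np.repeat(np.arange(config.n_blocks), dis_sizes)

    # tree numbers: block prefix of depth-1 segments under a common root,
    # one unique leaf segment per disease
    tree_numbers: dict[str, set] = {}
    for b in range(config.n_blocks):
        if config.tree_depth == 2:
            # no room for a root + block segment: fold them into one
            prefix = f"C{b + 1:02d}"
        else:
            mids = [str(tree_rng.integers(100, 1000))
                    for _ in range(config.tree_depth - 3)]
            prefix = ".".join(["C", f"{b + 1:02d}", *mids])
        members = np.flatnonzero(dis_block == b)
        leaves = tree_rng.choice(np.arange(100, 1000), size=len(members),
                                 replace=False)
        for j, leaf in zip(members, leaves):
            tree_numbers[disease_ids[j]] = {f"{prefix}.{leaf}"}
    tree_numbers = {d: tree_numbers[d] for d in disease_ids}

    AS = np.zeros((config.n_lncrna, config.n_disease), dtype=np.int8)
    for b in range(config.n_blocks):
        lncs = np.flatnonzero(lnc_block == b)
        diss = np.flatnonzero(dis_block == b)
        if config.assoc_per_block < max(len(lncs), len(diss)):
            raise ValueError(
                f"assoc_per_block={config.assoc_per_block} cannot cover the "
                f"{len(lncs)} lncRNAs and {len(diss)} diseases of block {b}"
            )
        if config.assoc_per_block > len(lncs) * len(diss):
            raise ValueError(
                f"assoc_per_block={config.assoc_per_block} exceeds the "
                f"{len(lncs) * len(diss)} cells of block {b}"
            )
        # round-robin coverage: every lncRNA and disease of the block gets an
        # association
        lp = assoc_rng.permutation(lncs)
        dp = assoc_rng.permutation(diss)
        for t in range(max(len(lncs), len(diss))):
            AS[lp[t % len(lncs)], dp[t % len(diss)]] = 1
        # fill the block quota with uniformly random free in-block cells
        while AS[np.ix_(lncs, diss)].sum() < config.assoc_per_block:
            free = np.argwhere(AS[np.ix_(lncs, diss)] == 0)
            need = config.assoc_per_block - int(AS[np.ix_(lncs, diss)].sum())
            pick = free[assoc_rng.choice(len(free), size=need, replace=False)]
            AS[lncs[pick[:, 0]], diss[pick[:, 1]]] = 1

    # cross-block noise associations on free off-block cells
    if config.noise_assoc:
        off_block = (lnc_block[:, None] != dis_block[None, :]) & (AS == 0)
        free = np.argwhere(off_block)
        if config.noise_assoc > len(free):
            raise ValueError("not enough off-block cells for noise_assoc")
        pick = free[noise_rng.choice(len(free), size=config.noise_assoc,
                                     replace=False)]
        AS[pick[:, 0], pick[:, 1]] = 1

    dataset = AssociationDataset(lncrna_ids, disease_ids, AS)
    assert dataset.n_associations == config.n_associations
    return SyntheticBenchmark(
        dataset=dataset,
        tree_numbers=tree_numbers,
        lncrna_blocks={lncrna_ids[i]: int(lnc_block[i])
                       for i in range(config.n_lncrna)},
        disease_blocks={disease_ids[j]: int(dis_block[j])
                        for j in range(config.n_disease)},
    )


def permute_labels(dataset: AssociationDataset, seed: int) -> AssociationDataset:
    """Null model: reassign the association cells uniformly at random,
    preserving their total count and destroying the planted block signal."""
    rng = np.random.default_rng(seed)
    n = dataset.n_associations
    flat = rng.choice(dataset.nl * dataset.nd, size=n, replace=False)
    AS = np.zeros(dataset.nl * dataset.nd, dtype=np.int8)
    AS[flat] = 1
    return dataset.copy_with(AS.reshape(dataset.nl, dataset.nd))
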