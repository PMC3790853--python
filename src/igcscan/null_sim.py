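"""No-exchange simulation null.

Families are re-simulated along the fitted tree under GTR+Gamma(4)+I with
no interlocus exchange; the resulting replicate alignments provide the
null expectation for reticulate- and bimutational-site counts.  Replicate
streams are reproducible: the stream for replicate ``i`` is seeded from
``(seed, i)``, so the same pair always yields the same alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .family_io import AlignedFamily, LocusRecord
from .phylo import Tree
from .substitution import SubstitutionModel, evolve_along_tree, decode


@dataclass
class SimulationSpec:
    """What to simulate: tree, model, alignment length, replicate count."""

    tree: Tree
    model: SubstitutionModel
    length: int
    n_replicates: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("length must be positive")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


def replicate_rng(seed: int, replicate_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(replicate_index)]))


def simulate_alignment(spec: SimulationSpec, replicate_index: int = 0) -> dict[str, np.ndarray]:
    """Simulate one gapless replicate alignment over the tree's leaves.

    Each site independently draws the invariant class (probability p_inv)
    or a gamma rate category; the root is drawn from the stationary
    frequencies and evolved along every branch by the GTR transition
    probabilities.  Deterministic given ``(spec.seed, replicate_index)``;
    contains no interlocus exchange by construction.
    """
    rng = replicate_rng(spec.seed, replicate_index)
    return evolve_along_tree(spec.tree.node, spec.model, spec.length, rng)


def simulate_family(spec: SimulationSpec, replicate_index: int = 0,
                    template: AlignedFamily | None = None) -> AlignedFamily:
    """Like :func:`simulate_alignment` but packaged as an
    :class:`AlignedFamily` (member order and loci from ``template`` when
    given, otherwise synthetic loci on a single placeholder chromosome)."""
    leaves = simulate_alignment(spec, replicate_index)
    if template is not None:
        names = template.names
        members = list(template.members)
        col_map = template.col_map[:, : spec.length]
        if col_map.shape[1] != spec.length:
            raise ValueError("template shorter than simulated length")
    else:
        names = sorted(leaves)
        members = [
            LocusRecord("sim", n, "chrSim", i * (spec.length + 100),
                        i * (spec.length + 100) + spec.length)
            for i, n in enumerate(names)
        ]
        col_map = np.vstack([
            np.arange(m.start, m.start + spec.length) for m in members
        ])
    matrix = np.vstack([leaves[n] for n in names])
    fam_id = template.family_id if template is not None else "sim"
    return AlignedFamily(fam_id, members, matrix, col_map)


def write_replicates(spec: SimulationSpec, path_template: str) -> list[str]:
    """Write all replicates as multi-FASTA; ``path_template`` must contain
    ``{i}``.  Returns the paths written."""
    paths = []
    for i in range(spec.n_replicates):
        leaves = simulate_alignment(spec, i)
        p = path_template.format(i=i)
        with open(p, "w") as fh:
            for name in sorted(leaves):
                fh.write(f">{name}\n{decode(leaves[name])}\n")
        paths.append(p)
    return paths
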