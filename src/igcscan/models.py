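"""Model/Results front ends for the two per-family tests.

These wrap the functional machinery in :mod:`quartet_scan` and
:mod:`tracks_identity` in the familiar construct-fit-summarise shape:
build the model from an :class:`~igcscan.family_io.AlignedFamily`, call
``fit()`` and read estimates, intervals and P-values off the results
object.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .family_io import AlignedFamily
from .phylo import GTRFitResults, Tree, build_nj_tree, fit_substitution_model
from .quartet_scan import FamilyExcessTest, excess_test
from .substitution import SubstitutionModel
from .tracks_identity import FragmentCall, PermutationConfig, call_identity_tracks


@dataclass
class QuartetExcessResults:
    """Results of the quartet reticulate-site excess test."""

    test: FamilyExcessTest
    tree: Tree
    model: SubstitutionModel
    model_fit: GTRFitResults | None

    @property
    def p_value(self):
        return self.test.p_value

    @property
    def observed_R(self):
        return self.test.observed_R

    @property
    def expected_R(self):
        return self.test.expected_R

    @property
    def significant(self) -> bool:
        return self.test.p_value is not None and self.test.p_value <= 0.05

    def summary(self) -> str:
        out = self.test.summary()
        if self.model_fit is not None:
            out += "\n" + self.model_fit.summary()
        return out

    def plot(self, ax=None):
        """Observed R count against the simulated null distribution."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.test.sim_R, bins=20, color="0.7", label="simulated null")
        ax.axvline(self.test.observed_R, color="crimson", label="observed")
        lo, hi = self.test.ci_R
        ax.axvspan(lo, hi, color="crimson", alpha=0.15, label="95% bootstrap CI")
        ax.set_xlabel("family R-site count")
        ax.set_ylabel("replicates")
        ax.legend()
        return ax


class QuartetExcessModel:
    """Quartet-method test of interlocus exchange for one family.

    Parameters
    ----------
    family : AlignedFamily
        Gapless paralog alignment (optionally CpG-stripped).
    tree : Tree, optional
        Family tree; inferred by NJ/F84 when omitted.
    model : SubstitutionModel, optional
        Null simulation model; fitted by ML on the tree when omitted.
    """

    def __init__(self, family: AlignedFamily, tree: Tree | None = None,
                 model: SubstitutionModel | None = None):
        self.family = family
        self.tree = tree
        self.model = model

    def fit(self, n_boot: int = 100, n_sim: int = 100, seed: int = 0,
            tree_boot: int = 100) -> QuartetExcessResults:
        tree = self.tree
        if tree is None:
            tree = build_nj_tree(self.family, n_boot=tree_boot, seed=seed)
        model = self.model
        model_fit = None
        if model is None:
            model_fit = fit_substitution_model(self.family, tree)
            model = model_fit.model
            tree = model_fit.tree
        test = excess_test(self.family, tree, model, n_boot=n_boot,
                           n_sim=n_sim, seed=seed)
        return QuartetExcessResults(test=test, tree=tree, model=model,
                                    model_fit=model_fit)


@dataclass
class IdentityTrackResults:
    """Significant perfect-identity fragments of one family."""

    family: AlignedFamily
    fragments: list[FragmentCall]
    config: PermutationConfig

    @property
    def n_significant(self) -> int:
        return len(self.fragments)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.fragments:
            rows.append(
                {
                    "family": f.family_id,
                    "seq_a": f.pair[0],
                    "seq_b": f.pair[1],
                    "aln_start": f.start,
                    "aln_stop": f.stop,
                    "n_poly_spanned": f.n_poly_spanned,
                    "p_global": f.p_global,
                    "p_pairwise": f.p_pairwise,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"Family {self.family.family_id}: identity-track scan "
            f"({self.config.n_perm} permutations, alpha={self.config.alpha})",
            f"  significant fragments: {self.n_significant}",
        ]
        for f in self.fragments:
            lines.append(
                f"  {f.pair[0]} ~ {f.pair[1]}  aln {f.start}-{f.stop} "
                f"({f.n_poly_spanned} poly sites)  "
                f"P_global={f.p_global:.4f} P_pairwise={f.p_pairwise:.4f}"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Fragment positions along the alignment, one lane per pair."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pairs = sorted({f.pair for f in self.fragments})
        for lane, pair in enumerate(pairs):
            for f in self.fragments:
                if f.pair == pair:
                    ax.plot([f.start, f.stop], [lane, lane], lw=4)
        ax.set_yticks(range(len(pairs)))
        ax.set_yticklabels(["~".join(p) for p in pairs])
        ax.set_xlabel("alignment position (bp)")
        ax.set_xlim(0, self.family.length)
        return ax


class IdentityTrackModel:
    """GENECONV-style identity-fragment scan for one family."""

    def __init__(self, family: AlignedFamily):
        self.family = family

    def fit(self, n_perm: int = 10_000, alpha: float = 0.05,
            seed: int = 0) -> IdentityTrackResults:
        cfg = PermutationConfig(n_perm=n_perm, alpha=alpha, seed=seed)
        frags = call_identity_tracks(self.family, cfg)
        return IdentityTrackResults(family=self.family, fragments=frags, config=cfg)
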