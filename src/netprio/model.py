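"""Model/Results surface over the prioritization pipelines.

A prioritizer is constructed from data (network, seed genes, term
annotations); ``fit()`` runs the leave-one-out grid search over the
screening thresholds and returns a :class:`PrioritizationResults` with
the per-combination evaluation table, the tied optima, and a
``predict()`` that applies the selected thresholds to the full seed set.

    >>> model = RWRPrioritizer(network, seeds, annotations)   # doctest: +SKIP
    >>> res = model.fit(n_perm=100, rng_seed=7)               # doctest: +SKIP
    >>> print(res.summary())                                  # doctest: +SKIP
    >>> res.putative_genes()                                  # doctest: +SKIP
"""

from __future__ import annotations

from functools import cached_property
from typing import Mapping, Sequence

import pandas as pd

from .errors import ValidationError
from .network import RAW, SeedSet, WeightedNetwork, make_seed_set
from .records import CandidateRecord
from . import evaluation as _eval
from . import pipeline as _pipe
from . import rwr as _rwr
from . import screening as _screen
from . import shortest_paths as _sp
from .util import derived_seed


class _BasePrioritizer:
    """Shared construction: bind network, seeds and annotation profile."""

    method: str

    def __init__(
        self,
        network: WeightedNetwork,
        seeds: SeedSet | Sequence[str],
        annotations: _screen.AnnotationProfile | Mapping[str, Sequence[str]],
        scorer: str = _screen.NEIGHBORHOOD_HYPERGEOMETRIC,
        p_cutoff: float = _screen.DEFAULT_P_CUTOFF,
    ):
        self.network = network.with_mode(RAW)
        if isinstance(seeds, SeedSet):
            self.seeds = seeds
        else:
            self.seeds = make_seed_set(seeds, self.network)
        if isinstance(annotations, _screen.AnnotationProfile):
            self.profile = annotations
        else:
            self.profile = _screen.build_annotation_profile(
                annotations, self.network, scorer=scorer
            )
        self.p_cutoff = p_cutoff

    # subclasses provide the per-fold statistic computation
    def _fold_stats(self, fold_seeds: SeedSet, held_out: str, grid, n_perm: int,
                    rng_seed: int) -> _eval.FoldStats:
        raise NotImplementedError

    def fit(
        self,
        grid: Sequence[_eval.ParameterCombo] | None = None,
        n_perm: int = 100,
        rng_seed: int = 0,
    ) -> "PrioritizationResults":
        """Jackknife grid search; returns the fitted results object.

        ``n_perm`` defaults to 100 inside training (the permutation null is
        recomputed in every fold); the final prediction can use the full
        1000-set null.
        """
        grid = list(grid) if grid is not None else _eval.default_grid(self.method)
        if any(c.method != self.method for c in grid):
            raise ValidationError(f"grid contains combos for a different method")
        folds = [
            self._fold_stats(
                self.seeds.without(g), g, grid, n_perm,
                derived_seed(rng_seed, "fold", g),
            )
            for g in self.seeds.ids
        ]
        summaries = _eval.grid_search(folds, grid, p_cutoff=self.p_cutoff)
        return PrioritizationResults(
            model=self, summaries=summaries, fold_stats=folds,
            n_perm=n_perm, rng_seed=rng_seed,
        )

    def run(self, combo: _eval.ParameterCombo, n_perm: int = _screen.DEFAULT_N_PERM,
            rng_seed: int = 0) -> list[CandidateRecord]:
        """Execute the full screened pipeline on the complete seed set."""
        raise NotImplementedError


class RWRPrioritizer(_BasePrioritizer):
    """Random-walk-with-restart prioritizer with the three screening rules."""

    method = _eval.RWR

    def __init__(self, network, seeds, annotations,
                 scorer=_screen.NEIGHBORHOOD_HYPERGEOMETRIC,
                 p_cutoff=_screen.DEFAULT_P_CUTOFF,
                 restart_prob: float = 0.8, tolerance: float = 1e-6):
        super().__init__(network, seeds, annotations, scorer=scorer, p_cutoff=p_cutoff)
        self.config = _rwr.RWRConfig(restart_prob=restart_prob, tolerance=tolerance)

    def _fold_stats(self, fold_seeds, held_out, grid, n_perm, rng_seed):
        min_prwrp = min(c.prwrp for c in grid)
        return _pipe.compute_rwr_fold_stats(
            self.network, fold_seeds, held_out, self.profile,
            min_prwrp=min_prwrp, n_perm=n_perm, rng_seed=rng_seed,
            config=self.config,
        )

    def run(self, combo, n_perm=_screen.DEFAULT_N_PERM, rng_seed=0):
        thresholds = _screen.ScreeningThresholds(
            p_cutoff=self.p_cutoff, p_mis=combo.p_mis, p_mfs=combo.p_mfs
        )
        return _pipe.run_rwr_method(
            self.network, self.seeds, self.profile, combo.prwrp, thresholds,
            rng_seed=rng_seed, n_perm=n_perm, config=self.config,
        )


class SPPrioritizer(_BasePrioritizer):
    """Seed-pair shortest-path prioritizer with the three screening rules."""

    method = _eval.SP

    def __init__(self, network, seeds, annotations,
                 scorer=_screen.NEIGHBORHOOD_HYPERGEOMETRIC,
                 p_cutoff=_screen.DEFAULT_P_CUTOFF,
                 path_mode: str = _sp.ALL_TIES):
        super().__init__(network, seeds, annotations, scorer=scorer, p_cutoff=p_cutoff)
        self.path_mode = path_mode

    def _fold_stats(self, fold_seeds, held_out, grid, n_perm, rng_seed):
        return _pipe.compute_sp_fold_stats(
            self.network, fold_seeds, held_out, self.profile,
            n_perm=n_perm, rng_seed=rng_seed, path_mode=self.path_mode,
        )

    def run(self, combo, n_perm=_screen.DEFAULT_N_PERM, rng_seed=0):
        thresholds = _screen.ScreeningThresholds(
            p_cutoff=self.p_cutoff, p_mis=combo.p_mis, p_mfs=combo.p_mfs
        )
        return _pipe.run_sp_method(
            self.network, self.seeds, self.profile, thresholds,
            rng_seed=rng_seed, n_perm=n_perm, path_mode=self.path_mode,
        )


class PrioritizationResults:
    """Grid-search outcome: evaluation table, tied optima, prediction."""

    def __init__(self, model: _BasePrioritizer,
                 summaries: list[_eval.EvaluationSummary],
                 fold_stats: list[_eval.FoldStats],
                 n_perm: int, rng_seed: int):
        self.model = model
        self.summaries = summaries
        self.fold_stats = fold_stats
        self.n_perm = n_perm
        self.rng_seed = rng_seed

    @property
    def best(self) -> list[_eval.EvaluationSummary]:
        """All parameter combinations tied at the maximum mean F1-measure-R."""
        return _eval.best_combos(self.summaries)

    @property
    def params(self) -> _eval.ParameterCombo:
        """The first tied optimum (deterministic combo ordering)."""
        return self.best[0].combo

    @property
    def max_f1_r(self) -> float:
        return self.best[0].mean_f1_r

    @cached_property
    def frame(self) -> pd.DataFrame:
        """One row per grid point: thresholds and mean fold metrics."""
        rows = [
            {
                "method": s.combo.method,
                "prwrp": s.combo.prwrp,
                "p_mis": s.combo.p_mis,
                "p_mfs": s.combo.p_mfs,
                "mean_recall": s.mean_recall,
                "mean_precision": s.mean_precision,
                "mean_f1": s.mean_f1,
                "mean_f1_r": s.mean_f1_r,
                "n_folds": s.n_folds,
            }
            for s in self.summaries
        ]
        return pd.DataFrame(rows)

    def predict(self, combo: _eval.ParameterCombo | None = None,
                n_perm: int | None = None,
                rng_seed: int | None = None) -> list[CandidateRecord]:
        """Run the screened pipeline on the full seed set at the chosen optimum."""
        combo = combo or self.params
        return self.model.run(
            combo,
            n_perm=n_perm if n_perm is not None else self.n_perm,
            rng_seed=rng_seed if rng_seed is not None else
            derived_seed(self.rng_seed, "predict"),
        )

    def putative_genes(self, **kwargs) -> frozenset[str]:
        return _pipe.putative_genes(self.predict(**kwargs))

    def tied_outputs_coincide(self, n_perm: int | None = None) -> bool:
        """Re-run prediction at every tied optimum and report whether the
        putative sets are identical (the consistency check applied when the
        training objective ties across thresholds)."""
        sets = {
            self.putative_genes(combo=s.combo, n_perm=n_perm)
            for s in self.best
        }
        return len(sets) == 1

    def summary(self, top: int = 10) -> str:
        """Human-readable fit report."""
        lines = [
            f"{type(self.model).__name__} fit "
            f"({len(self.model.seeds)} seeds, {self.model.network.n_nodes} genes, "
            f"{len(self.summaries)} grid points, n_perm={self.n_perm})",
            "",
            f"max mean F1-measure-R = {self.max_f1_r:.6g} "
            f"achieved by {len(self.best)} combination(s):",
        ]
        shown = self.best[:6]
        for s in shown:
            c = s.combo
            thr = f"p_MIS={c.p_mis}, p_MFS={c.p_mfs}"
            if c.prwrp is not None:
                thr = f"pRWRp={c.prwrp:g}, " + thr
            lines.append(
                f"  {thr}  (recall={s.mean_recall:.4f}, "
                f"precision={s.mean_precision:.4f}, F1-R={s.mean_f1_r:.6g})"
            )
        if len(self.best) > len(shown):
            lines.append(f"  ... and {len(self.best) - len(shown)} more tied combination(s)")
        lines.append("")
        lines.append(f"top {min(top, len(self.summaries))} grid points:")
        lines.append(self.frame.head(top).to_string(index=False))
        return "\n".join(lines)
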