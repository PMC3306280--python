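"""statsmodels-style entry point: a model object built from data, a results
object carrying the fitted module ranking.

``ModulePrognosis`` bundles an expression dataset, a gene-set collection and
an interaction network.  ``fit()`` runs network construction, module
discovery and differential-expression ranking over the labeled samples and
returns a ``ModulePrognosisResults`` with the ranked modules, diagnostics
and a ``summary()`` table.  Prediction and evaluation (which refit the
pipeline on half-cohorts internally) hang off the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classifier as _clf
from . import io as _io
from .community import DEFAULT_MAX_SIZE, ModulePartition, discover_all
from .io import NON_RECURRENT, RECURRENT, ExpressionDataset, GeneSetCollection, InteractionNetwork
from .networks import WeightedGeneSetNetwork, build_networks
from .ranking import RankedModules, rank_modules, top_n_gene_union


class ModulePrognosis:
    """Module-based recurrence prognosis model.

    Parameters
    ----------
    dataset
        Preprocessed (probe-collapsed, imputed) expression dataset with
        recurrent / non_recurrent / unlabeled sample labels.
    gene_sets
        Functional gene sets (e.g. GO collections in GMT form) defining the
        per-set co-expression networks.
    interactions
        Undirected protein-interaction edges supplying the network topology.
    module_cap
        Maximum module size for the Girvan-Newman size-cap stopping rule.
    equal_var
        Pooled-variance t statistics instead of Welch.
    weighted_paths
        Use 1/weight edge lengths for the shortest paths inside the
        betweenness score (non-default variant).
    """

    def __init__(
        self,
        dataset: ExpressionDataset,
        gene_sets: GeneSetCollection,
        interactions: InteractionNetwork,
        module_cap: int = DEFAULT_MAX_SIZE,
        equal_var: bool = False,
        weighted_paths: bool = False,
    ) -> None:
        self.dataset = dataset
        self.gene_sets = gene_sets
        self.interactions = interactions
        self.module_cap = module_cap
        self.equal_var = equal_var
        self.weighted_paths = weighted_paths
        self._cache: dict = {}

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_files(
        cls,
        expression_path,
        gene_sets_path,
        interactions_path,
        label_path=None,
        impute_k: int = 10,
        include_samples=None,
        exclude_samples=None,
        **kwargs,
    ) -> "ModulePrognosis":
        """Read the standard text formats and run the preprocessing chain."""
        ds = _io.read_expression(expression_path, label_path)
        ds = _io.preprocess(ds, k=impute_k, include=include_samples, exclude=exclude_samples)
        return cls(
            dataset=ds,
            gene_sets=_io.read_gene_sets(gene_sets_path),
            interactions=_io.read_interactions(interactions_path),
            **kwargs,
        )

    @classmethod
    def from_cohort(cls, cohort, **kwargs) -> "ModulePrognosis":
        """Build from a synthetic cohort (see :mod:`modprog.simulate`)."""
        return cls(
            dataset=cohort.dataset,
            gene_sets=cohort.sets,
            interactions=cohort.ppi,
            **kwargs,
        )

    # -- fitting ------------------------------------------------------------

    def _labeled(self) -> list[str]:
        return [
            s
            for s in self.dataset.sample_ids
            if self.dataset.labels[s] in (RECURRENT, NON_RECURRENT)
        ]

    def fit(self, samples: list[str] | None = None) -> "ModulePrognosisResults":
        """Networks -> modules -> ranking over ``samples`` (default: all labeled)."""
        samples = list(samples) if samples is not None else self._labeled()
        group_a = [s for s in samples if self.dataset.labels[s] == RECURRENT]
        group_b = [s for s in samples if self.dataset.labels[s] == NON_RECURRENT]
        if len(group_a) < 2 or len(group_b) < 2:
            raise ValueError("need >= 2 samples per class among the fitted samples")
        networks = build_networks(
            self.dataset, self.gene_sets, self.interactions, samples, cache=self._cache
        )
        partition = discover_all(
            networks, max_size=self.module_cap, weighted_paths=self.weighted_paths
        )
        ranked = rank_modules(
            partition, self.dataset, group_a, group_b, equal_var=self.equal_var
        )
        return ModulePrognosisResults(
            model=self,
            samples=samples,
            networks=networks,
            partition=partition,
            ranked=ranked,
        )

    def _params(self, n_splits, n_grid, mode) -> _clf.PipelineParams:
        return _clf.PipelineParams(
            n_splits=n_splits,
            n_grid=tuple(n_grid),
            max_module_size=self.module_cap,
            mode=mode,
            equal_var=self.equal_var,
            weighted_paths=self.weighted_paths,
        )

    # -- prediction / evaluation -------------------------------------------

    def predict(
        self,
        test_samples,
        training_samples=None,
        n_splits: int = _clf.DEFAULT_N_SPLITS,
        n_grid=_clf.DEFAULT_N_GRID,
        seed: int = 0,
        mode: str = "full",
    ) -> pd.DataFrame:
        """<OP> scores for test tumours; higher means higher recurrence risk."""
        training = (
            list(training_samples)
            if training_samples is not None
            else [s for s in self._labeled() if s not in set(test_samples)]
        )
        scores = _clf.score_samples(
            list(test_samples),
            self.dataset,
            training,
            self.gene_sets,
            self.interactions,
            self._params(n_splits, n_grid, mode),
            base_seed=seed,
            cache=self._cache,
        )
        return pd.DataFrame(
            {"sample": [s.sample_id for s in scores], "score": [s.score for s in scores]}
        ).set_index("sample")

    def evaluate_loo(
        self,
        n_splits: int = _clf.DEFAULT_N_SPLITS,
        n_grid=_clf.DEFAULT_N_GRID,
        seed: int = 0,
        mode: str = "full",
    ) -> _clf.EvaluationReport:
        return _clf.leave_one_out(
            self.dataset,
            self.gene_sets,
            self.interactions,
            self._params(n_splits, n_grid, mode),
            base_seed=seed,
            cache=self._cache,
        )

    def evaluate_holdout(
        self,
        training_samples,
        test_samples,
        n_splits: int = _clf.DEFAULT_N_SPLITS,
        n_grid=_clf.DEFAULT_N_GRID,
        seed: int = 0,
        mode: str = "full",
    ) -> _clf.EvaluationReport:
        return _clf.evaluate_holdout(
            self.dataset,
            self.gene_sets,
            self.interactions,
            training_samples,
            test_samples,
            self._params(n_splits, n_grid, mode),
            base_seed=seed,
            cache=self._cache,
        )

    def evaluate_fixed(
        self,
        train_size: int,
        n_repeats: int = 5,
        n_splits: int = _clf.DEFAULT_N_SPLITS,
        n_grid=_clf.DEFAULT_N_GRID,
        seed: int = 0,
        mode: str = "full",
    ):
        return _clf.fixed_train_validation(
            self.dataset,
            self.gene_sets,
            self.interactions,
            train_size,
            n_repeats=n_repeats,
            params=self._params(n_splits, n_grid, mode),
            base_seed=seed,
            cache=self._cache,
        )


@dataclass
class ModulePrognosisResults:
    """Fitted module ranking plus the intermediate networks and partition."""

    model: ModulePrognosis
    samples: list[str]
    networks: list[WeightedGeneSetNetwork]
    partition: ModulePartition
    ranked: RankedModules

    @property
    def n_modules(self) -> int:
        return len(self.partition)

    def top_gene_union(self, n: int) -> set[str]:
        return top_n_gene_union(self.ranked, n)

    def to_frame(self) -> pd.DataFrame:
        return self.ranked.to_frame()

    def diagnostics(self) -> dict:
        """Descriptive statistics of the fitted partition and ranking."""
        sizes = [m.size for m in self.partition]
        ps = [e.p_value for e in self.ranked]
        top20_max_p = max(ps[: min(20, len(ps))]) if ps else float("nan")
        return {
            "n_networks": len(self.networks),
            "n_modules": len(sizes),
            "discarded_singletons": self.partition.discarded_singletons,
            "median_module_size": float(np.median(sizes)) if sizes else float("nan"),
            "max_module_size": max(sizes) if sizes else 0,
            "top20_max_p": float(top20_max_p),
        }

    def summary(self, top: int = 10) -> str:
        """Human-readable fit summary: data shape, partition, top modules."""
        d = self.diagnostics()
        labels = self.model.dataset.labels.loc[self.samples]
        n_rec = int((labels == RECURRENT).sum())
        n_non = int((labels == NON_RECURRENT).sum())
        lines = [
            "Module-based prognosis fit",
            "=" * 60,
            f"samples:            {len(self.samples)} ({n_rec} recurrent, {n_non} non-recurrent)",
            f"gene sets:          {len(self.model.gene_sets)}",
            f"networks built:     {d['n_networks']}",
            f"modules (<= {self.model.module_cap:2d}):     {d['n_modules']} "
            f"(+{d['discarded_singletons']} singletons discarded)",
            f"median module size: {d['median_module_size']:.1f}",
            f"max p in top 20:    {d['top20_max_p']:.3g}",
            "-" * 60,
            f"{'rank':>4} {'set_id':<12} {'k':>3} {'SDS':>10} {'p':>10}  genes",
        ]
        for i, e in enumerate(self.ranked.top(top), start=1):
            genes = ",".join(e.module.genes[:4])
            if e.module.size > 4:
                genes += ",..."
            lines.append(
                f"{i:>4} {e.module.set_id:<12} {e.k:>3} {e.sds:>10.2f} {e.p_value:>10.3g}  {genes}"
            )
        lines.append("=" * 60)
        return "\n".join(lines)
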