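"""Monte-Carlo enrichment of catalogued functional sites inside fragments.

The null model samples, per repetition, ``n_sampled`` distinct nucleotide
positions uniformly without replacement from the ``total_positions``
positions of the concatenated extant rRNAs and counts how many fall in the
set of catalogued functional positions — the count is hypergeometric, with
analytic mean ``n_sampled * n_functional / total_positions``.  The observed
count is the number of unique functional positions covered by the fragment
intervals (in the same extant-species coordinates); the empirical p-value
uses the add-one permutation estimator.
"""

from __future__ import annotations

import json
import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .io import FunctionalSiteCatalog
from .repeats import Fragment
from .seq import Molecule


def observed_functional_count(
    intervals: Iterable[Fragment | tuple[Molecule | str, int, int]],
    catalog: FunctionalSiteCatalog,
) -> int:
    """Unique catalogued positions covered by the union of fragment intervals.

    ``intervals`` are in extant-species (catalogue) coordinates, either
    :class:`Fragment` objects or bare ``(molecule, start, end)`` tuples with
    1-based inclusive ends.
    """
    covered: dict[Molecule, set[int]] = defaultdict(set)
    for item in intervals:
        if isinstance(item, Fragment):
            mol, start, end = item.molecule, item.start, item.end
        else:
            mol, start, end = Molecule.coerce(item[0]), item[1], item[2]
        covered[mol].update(range(start, end + 1))
    catalog_mols = {mol for mol, _ in catalog.unique_positions()}
    for mol in covered:
        if mol not in catalog_mols:
            warnings.warn(
                f"molecule {mol.value} absent from catalogue; counts as zero coverage",
                stacklevel=2,
            )
    return sum(
        1 for mol, pos in catalog.unique_positions() if pos in covered.get(mol, ())
    )


def hypergeom_expectation(
    total_positions: int, n_functional: int, n_sampled: int
) -> float:
    """Expected functional hits when sampling without replacement: n*K/N."""
    if total_positions == 0:
        raise ZeroDivisionError("total_positions must be positive")
    return n_sampled * n_functional / total_positions


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed count, Monte-Carlo null distribution and analytic expectation."""

    total_positions: int
    n_functional: int
    n_sampled: int
    observed: int | None
    reps: int
    seed: int
    null_counts: np.ndarray
    analytic_mean: float

    def __post_init__(self) -> None:
        if self.observed is not None and not (
            0 <= self.observed <= min(self.n_functional, self.n_sampled)
        ):
            raise ValueError("observed out of [0, min(n_functional, n_sampled)]")
        if len(self.null_counts) != self.reps:
            raise ValueError("null_counts length must equal reps")

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_counts))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_counts, ddof=1))

    @property
    def empirical_p(self) -> float | None:
        """Add-one upper-tail permutation p-value, None without an observed count."""
        if self.observed is None:
            return None
        exceed = int(np.sum(self.null_counts >= self.observed))
        return (1 + exceed) / (self.reps + 1)

    def null_histogram(self) -> "np.ndarray":
        """(count, frequency) rows of the null distribution."""
        vals, freqs = np.unique(self.null_counts, return_counts=True)
        return np.column_stack([vals, freqs])

    def write_null_tsv(self, path) -> None:
        hist = self.null_histogram()
        with open(path, "w") as fh:
            fh.write("count\tfrequency\n")
            for val, freq in hist:
                fh.write(f"{val}\t{freq}\n")

    def to_dict(self) -> dict:
        return {
            "total_positions": self.total_positions,
            "n_functional": self.n_functional,
            "n_sampled": self.n_sampled,
            "observed": self.observed,
            "reps": self.reps,
            "seed": self.seed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "analytic_mean": self.analytic_mean,
            "empirical_p": self.empirical_p,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def summary(self) -> str:
        lines = [
            "Functional-site enrichment (sampling without replacement)",
            f"  positions sampled per rep: {self.n_sampled} of {self.total_positions}",
            f"  functional positions:      {self.n_functional}",
            f"  repetitions:               {self.reps} (seed {self.seed})",
            f"  null mean:                 {self.null_mean:.2f} "
            f"(analytic {self.analytic_mean:.2f}, sd {self.null_sd:.2f})",
        ]
        if self.observed is not None:
            lines.append(f"  observed:                  {self.observed}")
            lines.append(f"  empirical p (upper tail):  {self.empirical_p:.4g}")
        return "\n".join(lines)


def mc_null(
    total_positions: int,
    n_functional: int,
    n_sampled: int,
    reps: int = 10_000,
    seed: int = 0,
    observed: int | None = None,
    functional_positions: Sequence[int] | None = None,
) -> EnrichmentResult:
    """Monte-Carlo null for the functional-hit count, reproducible by seed.

    ``functional_positions`` fixes which 1-based positions are marked
    functional (defaults to ``1..n_functional``; by symmetry of uniform
    sampling the choice does not affect the distribution).
    """
    if not 0 <= n_sampled <= total_positions:
        raise ValueError("need 0 <= n_sampled <= total_positions")
    if not 0 <= n_functional <= total_positions:
        raise ValueError("need 0 <= n_functional <= total_positions")
    if functional_positions is None:
        functional_positions = range(1, n_functional + 1)
    else:
        functional_positions = list(functional_positions)
        if len(set(functional_positions)) != n_functional:
            raise ValueError("functional_positions must be n_functional distinct values")
    mask = np.zeros(total_positions + 1, dtype=bool)
    mask[np.fromiter(functional_positions, dtype=np.int64)] = True

    rng = np.random.default_rng(seed)
    counts = np.empty(reps, dtype=np.int64)
    for i in range(reps):
        sample = rng.choice(total_positions, size=n_sampled, replace=False)
        counts[i] = int(mask[sample + 1].sum())
    return EnrichmentResult(
        total_positions=total_positions,
        n_functional=n_functional,
        n_sampled=n_sampled,
        observed=observed,
        reps=reps,
        seed=seed,
        null_counts=counts,
        analytic_mean=hypergeom_expectation(total_positions, n_functional, n_sampled),
    )


class EnrichmentTest:
    """Enrichment test built from mapped fragments and a site catalogue.

    Parameters mirror the quantities of the sampling experiment: the total
    length of the concatenated extant rRNAs, the catalogue, and the fragment
    intervals in the catalogue's coordinates.  ``run(seed)`` draws the null
    and returns an :class:`EnrichmentResult`.
    """

    def __init__(
        self,
        intervals: Sequence[Fragment | tuple[Molecule | str, int, int]],
        catalog: FunctionalSiteCatalog,
        total_positions: int,
        reps: int = 10_000,
    ):
        from .repeats import union_span

        self.catalog = catalog
        self.total_positions = total_positions
        self.reps = reps
        self.observed = observed_functional_count(intervals, catalog)
        frags = [f for f in intervals if isinstance(f, Fragment)]
        if len(frags) == len(intervals):
            self.n_sampled = union_span(frags)
        else:
            covered: dict[Molecule, set[int]] = defaultdict(set)
            for item in intervals:
                if isinstance(item, Fragment):
                    covered[item.molecule].update(range(item.start, item.end + 1))
                else:
                    covered[Molecule.coerce(item[0])].update(
                        range(item[1], item[2] + 1)
                    )
            self.n_sampled = sum(len(v) for v in covered.values())
        self.n_functional = len(catalog.unique_positions())

    def run(self, seed: int = 0) -> EnrichmentResult:
        return mc_null(
            total_positions=self.total_positions,
            n_functional=self.n_functional,
            n_sampled=self.n_sampled,
            reps=self.reps,
            seed=seed,
            observed=self.observed,
        )


def hypergeom_distribution(total_positions: int, n_functional: int, n_sampled: int):
    """SciPy hypergeometric distribution of the null count (for cross-checks)."""
    return stats.hypergeom(M=total_positions, n=n_functional, N=n_sampled)
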