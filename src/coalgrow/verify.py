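"""Monte-Carlo verification of the closed-form neutral-model expectations.

Each experiment simulates many independent replicates, estimates the
summaries of interest (frequency-spectrum entries, segregating sites,
inter-coalescent intervals, TMRCA, star-mutation counts) with standard
errors, and reports a z-score against the corresponding closed form from
:mod:`coalgrow.theory`.  Two kinds of check coexist and must not be
confused:

* **exact identities** (SFS conservation, interval telescoping, the growth
  recurrence) hold on every replicate with zero tolerance -- a violation
  raises :class:`~coalgrow.errors.ConsistencyError`, meaning a bug;
* **stochastic checks** compare Monte-Carlo means to expectations; a row
  passes when |z| stays below the threshold (default 4, a crude familywise
  control for the few dozen simultaneous tests a report carries).

Every replicate draws from an independently seeded substream derived from
(seed, replicate index), so reports are bit-reproducible and independent of
execution order.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import theory
from .core import place_mutations, simulate_tree, tree_summaries
from .errors import ConsistencyError, InvalidParameterError
from .growth import check_recurrence, grow_tree

__all__ = [
    "MCReport",
    "run_direct_experiment",
    "run_growth_experiment",
    "run_equivalence_experiment",
]

DEFAULT_Z_THRESHOLD = 4.0
MIN_REPS = 100


@dataclass
class MCReport:
    """Result table of one verification experiment.

    ``table`` has one row per statistic with columns ``statistic, i, reps,
    mean, se, theory, z, passed``; ``i`` is the frequency class or interval
    index where applicable.  A degenerate statistic (zero variance) passes
    iff its mean equals the theory value exactly.
    """

    experiment: str
    params: dict
    seed: int
    z_threshold: float
    table: pd.DataFrame = field(repr=False)

    @property
    def exceedances(self) -> int:
        """Number of rows whose |z| met or exceeded the threshold."""
        return int((~self.table["passed"]).sum())

    @property
    def passed(self) -> bool:
        return self.exceedances == 0

    def summary(self) -> str:
        head = (
            f"experiment={self.experiment} params={self.params} seed={self.seed} "
            f"z_threshold={self.z_threshold}"
        )
        verdict = (
            "all statistics within threshold"
            if self.passed
            else f"{self.exceedances} statistic(s) exceeded |z| threshold"
        )
        return f"{head}\n{self.table.to_string(index=False)}\n{verdict}"

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            from . import __version__

            fh.write(f"# coalgrow {__version__}\n")
            fh.write(f"# experiment={self.experiment} seed={self.seed} "
                     f"z_threshold={self.z_threshold}\n")
            fh.write("# " + " ".join(f"{k}={v}" for k, v in self.params.items()) + "\n")
            self.table.to_csv(fh, sep="\t", index=False)


class _MeanAccumulator:
    """Running sums for vector-valued per-replicate statistics."""

    def __init__(self, size: int):
        self.count = 0
        self.total = np.zeros(size)
        self.total_sq = np.zeros(size)

    def add(self, x: np.ndarray) -> None:
        self.count += 1
        self.total += x
        self.total_sq += np.square(x)

    def mean(self) -> np.ndarray:
        return self.total / self.count

    def se(self) -> np.ndarray:
        # sample SD / sqrt(R)
        m = self.mean()
        var = np.maximum(self.total_sq / self.count - m**2, 0.0)
        var *= self.count / max(self.count - 1, 1)
        return np.sqrt(var / self.count)


def _row(statistic: str, i, reps: int, mean: float, se: float, th: float,
         threshold: float) -> dict:
    if se > 0:
        z = (mean - th) / se
        passed = abs(z) < threshold
    else:
        z = 0.0 if mean == th else math.inf
        passed = mean == th
    return {
        "statistic": statistic, "i": i, "reps": reps, "mean": mean,
        "se": se, "theory": th, "z": z, "passed": passed,
    }


def _two_sample_row(statistic: str, i, acc_a: _MeanAccumulator,
                    acc_b: _MeanAccumulator, idx: int, th: float,
                    threshold: float) -> dict:
    ma, mb = acc_a.mean()[idx], acc_b.mean()[idx]
    sa, sb = acc_a.se()[idx], acc_b.se()[idx]
    pooled = math.hypot(sa, sb)
    if pooled > 0:
        z = (ma - mb) / pooled
        passed = abs(z) < threshold
    else:
        z = 0.0 if ma == mb else math.inf
        passed = ma == mb
    return {
        "statistic": statistic, "i": i, "reps": acc_a.count, "mean": ma - mb,
        "se": pooled, "theory": th, "z": z, "passed": passed,
    }


def _substreams(seed: int, count: int):
    """Yield one independent generator per replicate, lazily."""
    for child in np.random.SeedSequence(seed).spawn(count):
        yield np.random.Generator(np.random.PCG64(child))


def _check_exact_identities(ms, sfs, tmrca, intervals) -> None:
    if int(sfs.sum()) != len(ms):
        raise ConsistencyError("SFS entries do not sum to the mutation count")
    if abs(tmrca - intervals.sum()) > 1e-9 * max(1.0, tmrca):
        raise ConsistencyError("t_MRCA does not equal the interval sum")


def _validate_common(theta: float, reps: int) -> None:
    if theta < 0:
        raise InvalidParameterError(f"theta must be >= 0, got {theta}")
    if reps < MIN_REPS:
        raise InvalidParameterError(
            f"need at least {MIN_REPS} replicates for usable standard errors, got {reps}"
        )


def run_direct_experiment(
    n: int,
    theta: float,
    reps: int,
    seed: int,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> MCReport:
    """Direct simulation at sample size n: SFS, S, intervals and TMRCA.

    Checks the Monte-Carlo means of s_i against theta/i, S against
    theta * H_{n-1}, each epoch length t_i against 1/(i(i-1)) and t_MRCA
    against (n-1)/n.  Per-replicate conservation identities are asserted
    exactly.
    """
    if n < 2:
        raise InvalidParameterError(f"sample size must be >= 2, got {n}")
    _validate_common(theta, reps)

    sfs_acc = _MeanAccumulator(n - 1)
    s_acc = _MeanAccumulator(1)
    int_acc = _MeanAccumulator(n - 1)  # intervals t_n .. t_2
    tmrca_acc = _MeanAccumulator(1)
    for rng in _substreams(seed, reps):
        tree = simulate_tree(n, rng)
        ms = place_mutations(tree, theta, rng)
        sfs = ms.sfs()
        tmrca, _, intervals = tree_summaries(tree)
        _check_exact_identities(ms, sfs, tmrca, intervals)
        sfs_acc.add(sfs)
        s_acc.add(np.array([len(ms)]))
        int_acc.add(intervals)
        tmrca_acc.add(np.array([tmrca]))

    rows = []
    sfs_mean, sfs_se = sfs_acc.mean(), sfs_acc.se()
    for i in range(1, n):
        rows.append(_row("s_i", i, reps, sfs_mean[i - 1], sfs_se[i - 1],
                         theta / i, z_threshold))
    rows.append(_row("S", None, reps, s_acc.mean()[0], s_acc.se()[0],
                     theory.expected_segregating_sites(n, theta), z_threshold))
    int_mean, int_se = int_acc.mean(), int_acc.se()
    for i in range(2, n + 1):
        j = n - i  # intervals are ordered t_n .. t_2
        rows.append(_row("t_i", i, reps, int_mean[j], int_se[j],
                         theory.expected_interval(i), z_threshold))
    rows.append(_row("t_mrca", None, reps, tmrca_acc.mean()[0],
                     tmrca_acc.se()[0], theory.expected_tmrca(n), z_threshold))
    return MCReport(
        experiment="direct",
        params={"n": n, "theta": theta, "reps": reps},
        seed=seed,
        z_threshold=z_threshold,
        table=pd.DataFrame(rows),
    )


def run_growth_experiment(
    n_start: int,
    n_end: int,
    theta: float,
    reps: int,
    seed: int,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> MCReport:
    """Repeated tip-extension growth n_start -> n_end with exact auditing.

    Every replicate simulates a mutated genealogy at ``n_start`` and grows
    it one tip at a time to ``n_end``; the size-class recurrence (including
    the realized singleton identity) is checked exactly at every step and a
    violation raises ConsistencyError.  The report compares, per
    intermediate sample size n: mean s_{i,*} against theta/n for every
    frequency class (plus a flatness statistic, the largest pairwise z
    between classes), the mean fraction of size-i mutations on the star
    path against i/n, and the mean extension-mutation count against
    theta/n.  The final spectrum at ``n_end`` is compared to theta/i.
    """
    if n_start < 2 or n_end <= n_start:
        raise InvalidParameterError(
            f"need 2 <= n_start < n_end, got n_start={n_start}, n_end={n_end}"
        )
    _validate_common(theta, reps)

    star_accs = {n: _MeanAccumulator(n - 1) for n in range(n_start, n_end)}
    frac_num = {n: np.zeros(n - 1) for n in range(n_start, n_end)}
    frac_den = {n: np.zeros(n - 1) for n in range(n_start, n_end)}
    frac_sq = {n: np.zeros(n - 1) for n in range(n_start, n_end)}
    ext_accs = {n: _MeanAccumulator(1) for n in range(n_start, n_end)}
    final_sfs_acc = _MeanAccumulator(n_end - 1)

    for rng in _substreams(seed, reps):
        tree = simulate_tree(n_start, rng)
        ms = place_mutations(tree, theta, rng)
        for n in range(n_start, n_end):
            sfs_before = ms.sfs()
            grown, rec = grow_tree(ms, rng)
            if not check_recurrence(ms, grown, rec):
                raise ConsistencyError(
                    f"growth recurrence violated at n={n} (seed={seed})"
                )
            star_accs[n].add(rec.star_counts.astype(float))
            ext_accs[n].add(np.array([float(rec.extension_mutation_count)]))
            nonzero = sfs_before > 0
            frac = np.zeros(n - 1)
            frac[nonzero] = rec.star_counts[nonzero] / sfs_before[nonzero]
            frac_num[n][nonzero] += frac[nonzero]
            frac_sq[n][nonzero] += frac[nonzero] ** 2
            frac_den[n][nonzero] += 1
            ms = grown
        final_sfs_acc.add(ms.sfs())

    rows = []
    sfs_mean, sfs_se = final_sfs_acc.mean(), final_sfs_acc.se()
    for i in range(1, n_end):
        rows.append(_row("final_s_i", i, reps, sfs_mean[i - 1], sfs_se[i - 1],
                         theta / i, z_threshold))
    for n in range(n_start, n_end):
        star_mean, star_se = star_accs[n].mean(), star_accs[n].se()
        th = theory.expected_star_count(n, theta)
        for i in range(1, n):
            rows.append(_row(f"s_star[n={n}]", i, reps, star_mean[i - 1],
                             star_se[i - 1], th, z_threshold))
        # flatness: largest pairwise z between frequency classes
        if n > 2:
            pair_z = 0.0
            for a in range(n - 1):
                for b in range(a + 1, n - 1):
                    pooled = math.hypot(star_se[a], star_se[b])
                    if pooled > 0:
                        pair_z = max(pair_z,
                                     abs(star_mean[a] - star_mean[b]) / pooled)
            rows.append({
                "statistic": f"s_star_flatness[n={n}]", "i": None, "reps": reps,
                "mean": pair_z, "se": math.nan, "theory": 0.0, "z": pair_z,
                "passed": pair_z < z_threshold,
            })
        rows.append(_row(f"ext_mutations[n={n}]", None, reps,
                         ext_accs[n].mean()[0], ext_accs[n].se()[0],
                         theta / n, z_threshold))
        for i in range(1, n):
            cnt = frac_den[n][i - 1]
            if cnt == 0:
                continue
            m = frac_num[n][i - 1] / cnt
            var = max(frac_sq[n][i - 1] / cnt - m**2, 0.0) * cnt / max(cnt - 1, 1)
            se = math.sqrt(var / cnt)
            rows.append(_row(f"star_fraction[n={n}]", i, int(cnt), m, se,
                             theory.star_probability(i, n), z_threshold))
    return MCReport(
        experiment="growth",
        params={"n_start": n_start, "n_end": n_end, "theta": theta, "reps": reps},
        seed=seed,
        z_threshold=z_threshold,
        table=pd.DataFrame(rows),
    )


def run_equivalence_experiment(
    n: int,
    theta: float,
    reps: int,
    seed: int,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> MCReport:
    """Direct simulation at n versus one growth step from n-1.

    The tip-extension construction claims distributional equivalence with a
    direct coalescent draw; this experiment compares the two arms' mean
    spectra bin by bin (pooled-variance two-sample z) and their mean TMRCA,
    with ``reps`` replicates per arm.
    """
    if n < 3:
        raise InvalidParameterError(f"equivalence needs n >= 3, got {n}")
    _validate_common(theta, reps)

    sfs_a = _MeanAccumulator(n - 1)
    sfs_b = _MeanAccumulator(n - 1)
    tm_a = _MeanAccumulator(1)
    tm_b = _MeanAccumulator(1)
    streams = _substreams(seed, 2 * reps)
    for rng in itertools.islice(streams, reps):
        tree = simulate_tree(n, rng)
        ms = place_mutations(tree, theta, rng)
        sfs_a.add(ms.sfs())
        tm_a.add(np.array([tree.t_mrca()]))
    for rng in streams:
        tree = simulate_tree(n - 1, rng)
        ms = place_mutations(tree, theta, rng)
        grown, rec = grow_tree(ms, rng)
        if not check_recurrence(ms, grown, rec):
            raise ConsistencyError("growth recurrence violated in equivalence run")
        sfs_b.add(grown.sfs())
        tm_b.add(np.array([grown.tree.t_mrca()]))

    rows = []
    for i in range(1, n):
        rows.append(_two_sample_row("s_i_direct_vs_grown", i, sfs_a, sfs_b,
                                    i - 1, 0.0, z_threshold))
    rows.append(_two_sample_row("t_mrca_direct_vs_grown", None, tm_a, tm_b,
                                0, 0.0, z_threshold))
    # one-sample rows against theory, for context
    ma, sa = sfs_a.mean(), sfs_a.se()
    mb, sb = sfs_b.mean(), sfs_b.se()
    for i in range(1, n):
        rows.append(_row("s_i_direct", i, reps, ma[i - 1], sa[i - 1],
                         theta / i, z_threshold))
        rows.append(_row("s_i_grown", i, reps, mb[i - 1], sb[i - 1],
                         theta / i, z_threshold))
    rows.append(_row("t_mrca_direct", None, reps, tm_a.mean()[0], tm_a.se()[0],
                     theory.expected_tmrca(n), z_threshold))
    rows.append(_row("t_mrca_grown", None, reps, tm_b.mean()[0], tm_b.se()[0],
                     theory.expected_tmrca(n), z_threshold))
    return MCReport(
        experiment="equivalence",
        params={"n": n, "theta": theta, "reps": reps},
        seed=seed,
        z_threshold=z_threshold,
        table=pd.DataFrame(rows),
    )
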