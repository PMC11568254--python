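"""Empirical r/m estimation and the simulation-based null model.

The r/m ratio compares nucleotide changes removed by recent homologous
recombination (r) against changes created by point mutation over the same
recent window (m), for one genome pair:

    r = (1 - ANI/100) * L_rec        m = d_rec * G

where L_rec is the total length of recombinant genes (pair identity >=
theta, default 99.8%), d_rec the average residual divergence of those genes
(their divergence was reset by the recombination event, so what they carry
now accumulated since it), and G the genome length. The rationale: before
recombining, those genes had diverged like the rest of the genome (~the
pair's ANI), so recombination purged about (1-ANI) per recombined base;
meanwhile point mutation has re-introduced d_rec per base genome-wide over
the same time.

The estimator degenerates in known ways that are flagged rather than
dropped: no recombinant genes gives ratio 0; perfectly identical recombinant
genes give m = 0 and an infinite ratio (the same mechanism behind the >100
outlier pairs seen in real collections); and above ~99.5% ANI there is no
signal over the background identity, so such pairs are marked unreliable.

The null model asks how many genes two genomes of a given ANI are expected
to share at 100% identity from clonal descent alone: daughter-daughter
pairs of the no-recombination population simulator are binned by realized
RBM ANI and the per-bin mean identical-gene fraction is the expectation
observed group fractions are compared against.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_core import Genome, RBMTable, UndefinedANIError, log
from .rbm_align import GenomeIndex, compute_rbm
from .ani_units import compute_ani
from .recomb import f100

FLAG_OK = "ok"
FLAG_NO_RECOMBINANT = "no_recombinant"
FLAG_INFINITE = "infinite"

RELIABLE_ANI_MAX = 99.5  # above this there is no identity signal to detect recombination


@dataclass
class RMResult:
    """r/m estimate for one genome pair; ratio may be 0, finite, or inf."""

    genome_a: str
    genome_b: str
    ani: float
    l_rec: int
    d_rec: float
    genome_length: float
    r: float
    m: float
    ratio: float
    flag: str


def _rm_terms(ani: float, l_rec: int, rec_divs: Sequence[float],
              genome_length: float) -> tuple[float, float, float, str]:
    """Shared r/m arithmetic. ``rec_divs`` are per-gene residual divergence
    fractions of the recombinant genes (possibly empty)."""
    r = (1.0 - ani / 100.0) * l_rec
    if not len(rec_divs):
        return 0.0, 0.0, 0.0, FLAG_NO_RECOMBINANT
    d_rec = float(np.mean(rec_divs))
    m = d_rec * genome_length
    if m == 0.0:
        return r, 0.0, float("inf"), FLAG_INFINITE
    return r, m, r / m, FLAG_OK


def estimate_rm(
    rbm_ab: RBMTable,
    ani: float | None = None,
    genome_length: float | None = None,
    theta: float = 99.8,
    weighted: bool = False,
    ani_mode: str = "genome",
) -> RMResult:
    """Estimate r and m for one genome pair from its RBM table.

    ``ani`` defaults to the table's own RBM ANI; ``genome_length`` must be
    supplied by the caller (use the mean of the two genome lengths for
    asymmetric pairs, see :func:`pair_genome_length`). ``weighted`` switches
    d_rec from the unweighted per-gene mean divergence to a length-weighted
    mean. ``ani_mode='non_recombined'`` replaces the whole-genome ANI in the
    r term with the ANI of the non-recombinant genes only, which removes the
    recombined genes' own pull on the baseline divergence.
    """
    if ani is None:
        ani = compute_ani(rbm_ab)
    if genome_length is None:
        raise ValueError("genome_length is required (e.g. pair_genome_length)")
    if ani >= 100.0:
        raise UndefinedANIError(
            f"r/m undefined at ANI {ani} (no divergence signal): pair "
            f"({rbm_ab.genome_a}, {rbm_ab.genome_b})"
        )
    ident = rbm_ab.identities
    lens = np.array([p.length_a for p in rbm_ab.pairs], dtype=float)
    rec = ident >= theta
    if ani_mode == "non_recombined":
        if (~rec).any():
            ani = float(np.average(ident[~rec], weights=rbm_ab.aln_lens[~rec]))
    elif ani_mode != "genome":
        raise ValueError(f"unknown ani_mode {ani_mode!r}")
    l_rec = int(lens[rec].sum())
    divs = 1.0 - ident[rec] / 100.0
    if weighted and rec.any():
        divs = np.full(int(rec.sum()), np.average(divs, weights=lens[rec]))
    r, m, ratio, flag = _rm_terms(ani, l_rec, divs, genome_length)
    d_rec = float(np.mean(divs)) if rec.any() else 0.0
    return RMResult(rbm_ab.genome_a, rbm_ab.genome_b, float(ani), l_rec, d_rec,
                    genome_length, r, m, ratio, flag)


def pair_genome_length(genome_a: Genome, genome_b: Genome) -> float:
    """Genome length G for the m term: mean of the two total lengths."""
    return 0.5 * (genome_a.total_length + genome_b.total_length)


def rm_vs_ani(results: Iterable[RMResult]) -> pd.DataFrame:
    """Long-format table of r/m estimates against pair ANI.

    Unordered pairs are deduplicated; pairs above ~99.5% ANI are flagged
    unreliable (recombination cannot be separated from background identity
    there).
    """
    seen = set()
    rows = []
    for res in results:
        key = frozenset((res.genome_a, res.genome_b))
        if key in seen:
            continue
        seen.add(key)
        rows.append({
            "genome_a": res.genome_a, "genome_b": res.genome_b, "ani": res.ani,
            "l_rec": res.l_rec, "d_rec": res.d_rec, "G": res.genome_length,
            "r": res.r, "m": res.m, "rm_ratio": res.ratio, "flag": res.flag,
            "unreliable": res.ani > RELIABLE_ANI_MAX,
        })
    return pd.DataFrame(rows, columns=["genome_a", "genome_b", "ani", "l_rec",
                                       "d_rec", "G", "r", "m", "rm_ratio",
                                       "flag", "unreliable"])


# ---------------------------------------------------------------------------
# null model: expected identical-gene fraction vs ANI
# ---------------------------------------------------------------------------


@dataclass
class NullCurve:
    """Expected identical-gene fraction per realized-ANI bin, with
    Monte-Carlo standard errors and per-bin pair counts."""

    table: pd.DataFrame  # columns: bin_center, mean_fraction, se, n

    def at(self, ani: float) -> pd.Series | None:
        """The bin covering ``ani``, or None if outside the curve."""
        if self.table.empty:
            return None
        width = self._bin_width()
        hit = self.table.loc[(self.table.bin_center - ani).abs() <= width / 2 + 1e-9]
        return hit.iloc[0] if not hit.empty else None

    def _bin_width(self) -> float:
        centers = np.sort(self.table.bin_center.unique())
        return float(np.min(np.diff(centers))) if len(centers) > 1 else 0.1


def pair_identical_stats(
    genomes: Sequence[Genome],
    pairs: Sequence[tuple[str, str]] | None = None,
    theta: float = 100.0,
) -> pd.DataFrame:
    """Realized RBM ANI and identical-gene fraction for genome pairs.

    By default every unordered pair of ``genomes`` is evaluated; k-mer
    indexes are built once per genome and shared across the pairings.
    """
    by_id = {g.genome_id: g for g in genomes}
    if pairs is None:
        pairs = [(a.genome_id, b.genome_id) for a, b in combinations(genomes, 2)]
    indexes: dict[str, GenomeIndex] = {}
    rows = []
    for ga, gb in pairs:
        for gid in (ga, gb):
            if gid not in indexes:
                indexes[gid] = GenomeIndex.build(by_id[gid])
        table = compute_rbm(by_id[ga], by_id[gb],
                            index_a=indexes[ga], index_b=indexes[gb])
        rows.append({"genome_a": ga, "genome_b": gb,
                     "ani": compute_ani(table),
                     "identical_fraction": f100(table, theta=theta)})
    return pd.DataFrame(rows)


def bin_identical_fractions(stats: pd.DataFrame, bin_width: float = 0.1) -> NullCurve:
    """Bin per-pair identical-gene fractions by realized ANI."""
    centers = np.round(np.round(stats.ani / bin_width) * bin_width, 6)
    rows = []
    for center, sub in stats.groupby(centers):
        frac = sub.identical_fraction.to_numpy()
        rows.append({
            "bin_center": float(center),
            "mean_fraction": float(frac.mean()),
            "se": float(frac.std(ddof=1) / np.sqrt(len(frac))) if len(frac) > 1 else np.nan,
            "n": int(len(frac)),
        })
    return NullCurve(pd.DataFrame(rows, columns=["bin_center", "mean_fraction",
                                                 "se", "n"]))


def expected_identical_curve(
    genomes: Sequence[Genome],
    bin_width: float = 0.1,
    theta: float = 100.0,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> NullCurve:
    """Null expectation for the identical-gene fraction as a function of ANI.

    ``genomes`` should be daughters of a no-recombination simulated
    population; all daughter-daughter pairs (or the supplied subset) are
    evaluated and binned by their realized RBM ANI.
    """
    stats = pair_identical_stats(genomes, pairs=pairs, theta=theta)
    curve = bin_identical_fractions(stats, bin_width=bin_width)
    log.info("null curve: %d pairs in %d bins", len(stats), len(curve.table))
    return curve


def excess_recombination(observed: pd.DataFrame, curve: NullCurve) -> pd.DataFrame:
    """Observed-minus-expected identical-gene fractions.

    ``observed`` needs columns ``ani`` and ``fraction`` (plus any id
    columns, which are passed through). Comparisons whose ANI falls outside
    the null curve are flagged and get no excess value.
    """
    rows = []
    for _, row in observed.iterrows():
        bin_row = curve.at(float(row.ani))
        out = dict(row)
        if bin_row is None:
            out.update({"null_mean": np.nan, "null_se": np.nan,
                        "excess": np.nan, "flag": "ani_outside_null_curve"})
        else:
            out.update({"null_mean": bin_row.mean_fraction, "null_se": bin_row.se,
                        "excess": float(row.fraction) - float(bin_row.mean_fraction),
                        "flag": FLAG_OK})
        rows.append(out)
    return pd.DataFrame(rows)


def write_null_curve(curve: NullCurve, path) -> None:
    curve.table.to_csv(path, sep="\t", index=False)


def read_null_curve(path) -> NullCurve:
    return NullCurve(pd.read_csv(path, sep="\t"))
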