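"""Recombinant-gene classification and genome-wide recombination accounting.

For a focal genome pair, each RBM gene pair is classified by nucleotide
identity against a threshold theta (default 99.8%, inclusive):

* ``recombinant_pair`` — identity >= theta within the pair: a recent
  homologous recombination event between the two genomes (or insufficient
  divergence time); a proxy for cohesion.
* ``recombinant_third`` — below theta within the pair but >= theta to its
  RBM counterpart in some third genome of the collection: recent exchange
  with an outside partner; a proxy for diversification. The best-identity
  third partner is recorded.
* ``non_recombinant`` — below theta everywhere: sequence divergence
  attributable to point mutation.

On top of the classification this module computes F100-style identical-gene
fractions, cumulative identical-gene fractions against genome groups defined
by unit membership (same genomovar, other genomovars of the phylogroup,
other phylogroups, other species, ...), reconstruction of presumed
recombined segments as maximal runs of consecutive recombinant genes, a
sliding-window view of recombination along the genome, and a chi-square
test for functional (COG category) bias of recombinant genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from statsmodels.stats.multitest import multipletests

from .io_core import AnnotationMap, Genome, RBMTable, log
from .rbm_align import RBMCollection
from .ani_units import UnitAssignment

RECOMBINANT_PAIR = "recombinant_pair"
RECOMBINANT_THIRD = "recombinant_third"
NON_RECOMBINANT = "non_recombinant"

CLASS_COLUMNS = ["genome_a", "genome_b", "gene_a", "gene_b", "identity",
                 "klass", "partner_genome", "partner_identity", "partner_unit"]


def _check_theta(theta: float) -> None:
    if not 90.0 < theta <= 100.0:
        raise ValueError(f"identity threshold theta={theta} outside (90, 100]")


def classify_genes(
    rbm_ab: RBMTable,
    collection: RBMCollection | None = None,
    theta: float = 99.8,
    units: UnitAssignment | None = None,
) -> pd.DataFrame:
    """Classify the RBM genes of a focal pair into the three categories.

    The third-partner search uses each third genome's own RBM pairing with
    the focal genes (no transitive chains); both members of the focal pair
    are probed and the best partner is recorded. If ``units`` is given the
    partner's unit labels are attached (genomovar/phylogroup of the partner
    genome), which is what the cohesion-vs-diversification accounting needs.
    """
    _check_theta(theta)
    third_ids: list[str] = []
    if collection is not None:
        third_ids = [g for g in collection.genome_ids
                     if g not in (rbm_ab.genome_a, rbm_ab.genome_b)]
    rows = []
    for p in rbm_ab.pairs:
        klass = NON_RECOMBINANT
        partner = None
        partner_ident = np.nan
        if p.identity >= theta:
            klass = RECOMBINANT_PAIR
        else:
            best = None
            for third in third_ids:
                for gid, gene in ((rbm_ab.genome_a, p.gene_a), (rbm_ab.genome_b, p.gene_b)):
                    hit = collection.identity_of(gid, gene, third)
                    if hit is not None and hit[0] >= theta:
                        if best is None or hit[0] > best[0]:
                            best = (hit[0], third)
            if best is not None:
                klass = RECOMBINANT_THIRD
                partner_ident, partner = best
        unit = ""
        if partner is not None and units is not None:
            unit = "%s/%s" % (units.unit_of(partner, "phylogroup"),
                              units.unit_of(partner, "genomovar"))
        rows.append({
            "genome_a": rbm_ab.genome_a, "genome_b": rbm_ab.genome_b,
            "gene_a": p.gene_a, "gene_b": p.gene_b, "identity": p.identity,
            "klass": klass, "partner_genome": partner or "",
            "partner_identity": partner_ident, "partner_unit": unit,
        })
    return pd.DataFrame(rows, columns=CLASS_COLUMNS)


def f100(rbm_ab: RBMTable, theta: float = 100.0) -> float:
    """Fraction of RBM gene pairs at >= theta percent identity.

    With the default theta=100 this is the F100 score (fraction of shared
    identical genes); theta=99.8 gives the recombinant-gene fraction.
    """
    if not rbm_ab.pairs:
        raise ValueError(
            f"F-score undefined: no RBM pairs between {rbm_ab.genome_a} "
            f"and {rbm_ab.genome_b}"
        )
    return float(np.mean(rbm_ab.identities >= theta))


# ---------------------------------------------------------------------------
# group-wise cumulative identical-gene fractions
# ---------------------------------------------------------------------------

GROUPS = ("A", "B", "C", "D", "E", "F")


def group_members(units: UnitAssignment, focal_id: str, group: str
                  ) -> list[tuple[str, list[str]]]:
    """Comparison genome sets for a focal genome, by group label.

    A: genomes of the same genomovar. B: each separate genomovar of the same
    phylogroup (one set per genomovar, own genomovar excluded). C: each
    separate genomovar of the other phylogroups of the species. D: genomes
    of the other species. E: the whole phylogroup excluding the focal
    genomovar (union of B). F: the whole species excluding the focal
    phylogroup (union of C). Returns (subgroup label, member ids) pairs;
    the focal genome itself is never a member.
    """
    df = units.assignments
    me = df.loc[df.genome_id == focal_id]
    if me.empty:
        raise KeyError(focal_id)
    gv, pg, sp = me.iloc[0].genomovar, me.iloc[0].phylogroup, me.iloc[0].species
    others = df.loc[df.genome_id != focal_id]
    if group == "A":
        ids = others.loc[others.genomovar == gv, "genome_id"].tolist()
        return [(gv, ids)] if ids else []
    if group == "B":
        sub = others.loc[(others.phylogroup == pg) & (others.genomovar != gv)]
        return [(g, s.genome_id.tolist()) for g, s in sub.groupby("genomovar")]
    if group == "C":
        sub = others.loc[(others.species == sp) & (others.phylogroup != pg)]
        return [(g, s.genome_id.tolist()) for g, s in sub.groupby("genomovar")]
    if group == "D":
        ids = others.loc[others.species != sp, "genome_id"].tolist()
        return [("other_species", ids)] if ids else []
    if group == "E":
        ids = others.loc[(others.phylogroup == pg) & (others.genomovar != gv),
                         "genome_id"].tolist()
        return [(pg, ids)] if ids else []
    if group == "F":
        ids = others.loc[(others.species == sp) & (others.phylogroup != pg),
                         "genome_id"].tolist()
        return [(sp, ids)] if ids else []
    raise ValueError(f"unknown group {group!r} (expected one of {GROUPS})")


def group_identical_fraction(
    focal: Genome,
    members: Sequence[str],
    collection: RBMCollection,
    theta: float = 99.8,
    denominator: str = "genome",
) -> float:
    """Cumulative fraction of the focal genome's genes identical (>= theta)
    to their RBM counterpart in at least one member of the group.

    Union semantics: a gene is counted once no matter how many members share
    it. ``denominator='genome'`` divides by all genes of the focal genome;
    ``denominator='rbm'`` divides by the genes with an RBM pair in at least
    one member.
    """
    _check_theta(theta)
    hit: set[str] = set()
    covered: set[str] = set()
    for member in members:
        table = collection.table(focal.genome_id, member)
        if table is None:
            continue
        oriented_a = table.genome_a == focal.genome_id
        for p in table.pairs:
            gene = p.gene_a if oriented_a else p.gene_b
            covered.add(gene)
            if p.identity >= theta:
                hit.add(gene)
    denom = focal.n_genes if denominator == "genome" else len(covered)
    if denom == 0:
        raise ValueError("no genes in denominator")
    return len(hit) / denom


def fig_groups_table(
    genomes: Sequence[Genome],
    collection: RBMCollection,
    units: UnitAssignment,
    theta: float = 99.8,
    denominator: str = "genome",
) -> pd.DataFrame:
    """Long-format table of cumulative identical-gene fractions: one row per
    (focal genome, group, subgroup). Empty groups are skipped with a log
    entry."""
    by_id = {g.genome_id: g for g in genomes}
    rows = []
    for gid, focal in by_id.items():
        for group in GROUPS:
            sets = group_members(units, gid, group)
            if not sets:
                log.info("fig_groups_table: genome %s has empty group %s", gid, group)
                continue
            for label, members in sets:
                rows.append({
                    "focal": gid, "group": group, "subgroup": label,
                    "n_members": len(members),
                    "fraction": group_identical_fraction(
                        focal, members, collection, theta, denominator),
                })
    return pd.DataFrame(rows, columns=["focal", "group", "subgroup", "n_members",
                                       "fraction"])


# ---------------------------------------------------------------------------
# segments and windows
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Segment:
    """A maximal run of consecutive recombinant-pair genes on one contig."""

    contig: str
    first_gene: str
    last_gene: str
    first_index: int
    last_index: int
    gene_count: int
    span_bp: int


def build_segments(classification: pd.DataFrame, genome: Genome
                   ) -> tuple[list[Segment], pd.DataFrame]:
    """Reconstruct presumed recombined segments for a classified pair.

    Runs are maximal stretches of consecutive ``recombinant_pair`` genes in
    the focal genome's gene order; genes without an RBM pair (accessory with
    respect to the pair) and RBM genes of any other class both break runs —
    a homologous tract cannot span a gene absent from the partner. The span
    is end of last gene minus start of first gene. Returns the segments and
    a histogram table of segment lengths binned by gene count.
    """
    klass_by_gene = dict(zip(classification.gene_a, classification.klass))
    segments: list[Segment] = []
    current: list[int] = []
    genes = genome.genes
    prev_contig = None
    for i, g in enumerate(genes):
        is_rec = klass_by_gene.get(g.gene_id) == RECOMBINANT_PAIR
        if is_rec and g.contig_id == prev_contig and current:
            current.append(i)
        elif is_rec:
            if current:
                segments.append(_make_segment(genes, current))
            current = [i]
        else:
            if current:
                segments.append(_make_segment(genes, current))
            current = []
        prev_contig = g.contig_id
    if current:
        segments.append(_make_segment(genes, current))
    hist = (
        pd.Series([s.gene_count for s in segments], dtype=int)
        .value_counts().sort_index().rename_axis("gene_count")
        .reset_index(name="n_segments")
    )
    return segments, hist


def _make_segment(genes, idx: list[int]) -> Segment:
    first, last = genes[idx[0]], genes[idx[-1]]
    return Segment(
        contig=first.contig_id, first_gene=first.gene_id, last_gene=last.gene_id,
        first_index=idx[0], last_index=idx[-1], gene_count=len(idx),
        span_bp=last.end - first.start,
    )


def segments_to_frame(segments: Sequence[Segment]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in segments],
                        columns=["contig", "first_gene", "last_gene", "first_index",
                                 "last_index", "gene_count", "span_bp"])


def windowed_recombination(
    classification: pd.DataFrame,
    genome: Genome,
    ani: float,
    window: int = 200_000,
    step: int = 100_000,
) -> pd.DataFrame:
    """Sliding-window recombination assessment along the focal genome.

    Per window (per contig; the last partial window is kept and flagged):
    the fraction of gene bp classified recombinant_pair, and the window r/m
    (recombination-purged vs mutation-created nucleotide changes restricted
    to the window's genes and span). Used to ask whether recombination
    affects every sizable region of the genome rather than a few hotspots.
    """
    if window < 10_000:
        raise ValueError("window must be at least 10 kb")
    from .rm_null import _rm_terms  # shared arithmetic, avoids circular import

    ident_by_gene = dict(zip(classification.gene_a, classification.identity))
    klass_by_gene = dict(zip(classification.gene_a, classification.klass))
    rows = []
    for contig_id, seq in genome.contigs:
        clen = len(seq)
        genes = [g for g in genome.genes if g.contig_id == contig_id]
        start = 0
        while True:
            end = min(start + window, clen)
            wgenes = [g for g in genes if g.start >= start and g.start < end]
            gene_bp = sum(g.length for g in wgenes)
            rec = [g for g in wgenes
                   if klass_by_gene.get(g.gene_id) == RECOMBINANT_PAIR]
            rec_bp = sum(g.length for g in rec)
            rec_divs = [1.0 - ident_by_gene[g.gene_id] / 100.0 for g in rec]
            r, m, ratio, flag = _rm_terms(ani, rec_bp, rec_divs, end - start)
            rows.append({
                "contig": contig_id, "start": start, "end": end,
                "partial": end - start < window,
                "gene_bp": gene_bp, "recombinant_bp": rec_bp,
                "recombinant_bp_fraction": rec_bp / gene_bp if gene_bp else np.nan,
                "r": r, "m": m, "rm_ratio": ratio, "flag": flag,
            })
            if end >= clen:
                break
            start += step
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# functional (COG) bias
# ---------------------------------------------------------------------------


def cog_bias(
    classifications: pd.DataFrame | Iterable[pd.DataFrame],
    annotations: AnnotationMap,
    theta: float = 99.8,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test each COG category for enrichment among recombinant genes.

    Gene occurrences across all supplied pair classifications are split into
    recombinant (pair identity >= theta) vs non-recombinant, and each
    category is tested with a one-sided 2x2 chi-square (no continuity
    correction; the side is chosen by the sign of the enrichment) followed
    by Benjamini-Hochberg correction across categories. Categories with a
    zero marginal are excluded and logged.
    """
    if isinstance(classifications, pd.DataFrame):
        cls = classifications
    else:
        cls = pd.concat(list(classifications), ignore_index=True)
    if cls.empty:
        raise ValueError("no classified genes supplied")
    cats = cls.gene_a.map(lambda g: annotations.get(g, "unannotated"))
    is_rec = cls.identity >= theta
    table = pd.crosstab(cats, is_rec)
    for col in (True, False):
        if col not in table.columns:
            table[col] = 0
    n_rec, n_non = int(table[True].sum()), int(table[False].sum())
    rows = []
    for cat, row in table.iterrows():
        a, c = int(row[True]), int(row[False])  # in-category counts
        b, d = n_rec - a, n_non - c
        if a + c == 0 or b + d == 0 or n_rec == 0 or n_non == 0:
            log.info("cog_bias: category %s excluded (zero marginal)", cat)
            continue
        obs = np.array([[a, b], [c, d]], dtype=float)
        chi2, p_two, _, _ = chi2_contingency(obs, correction=False)
        enriched = a / n_rec > c / n_non
        p_one = p_two / 2.0 if enriched else 1.0 - p_two / 2.0
        rows.append({"category": cat, "recombinant_in": a, "recombinant_out": b,
                     "non_recombinant_in": c, "non_recombinant_out": d,
                     "chi2": chi2, "enriched": enriched, "p_value": p_one})
    if len(rows) < 2:
        raise ValueError("cog_bias requires at least two categories with "
                         "nonzero totals")
    out = pd.DataFrame(rows)
    out["q_value"] = multipletests(out.p_value, method="fdr_bh")[1]
    out["significant"] = out.q_value < alpha
    return out.sort_values("q_value").reset_index(drop=True)
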