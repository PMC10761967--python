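"""Selection-site partition statistics and a counting-method dN/dS estimator.

Two questions from the screen's follow-up are answered here. First: are
externally called selection sites (MEME/FEL/FUBAR-style analyses, consumed
as a TSV) enriched in the exons shared by all isoforms relative to the exons
private to the long isoforms? That is a per-partition rate comparison backed
by the classic pooled two-proportion z test. Second: what is the gene-level
omega = dN/dS? Here it is estimated with the Nei-Gojobori (1986) counting
method with Jukes-Cantor correction, a deliberately simple, transparent
estimator (not a maximum-likelihood codon model); its known biases are
documented in the methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from typing import Sequence

from Bio.Data import CodonTable
from Bio.Seq import Seq
from scipy.stats import norm

from .errors import DegenerateProportionsError
from .seqio import ExonPartitionTable, SiteCall, SiteCallSet

NUCLEOTIDES = "ACGT"
UNASSIGNED = "unassigned"

_TABLE1 = CodonTable.unambiguous_dna_by_id[1]
_STOPS = frozenset(_TABLE1.stop_codons)
_AA = dict(_TABLE1.forward_table)  # sense codons only


# ---------------------------------------------------------------------------
# Partition rates


@dataclass(frozen=True)
class PartitionRow:
    """Counts and rates of selected sites within one exon partition."""

    label: str
    length_aa: int
    n_positive: int
    n_negative: int

    @property
    def rate_positive(self) -> float:
        """Positive-site rate in percent, 1 decimal (reporting convention)."""
        return round(100.0 * self.n_positive / self.length_aa, 1)

    @property
    def rate_negative(self) -> float:
        return round(100.0 * self.n_negative / self.length_aa, 1)


@dataclass(frozen=True)
class PartitionCounts:
    rows: tuple[PartitionRow, ...]
    unassigned_positive: int
    unassigned_negative: int
    method: str

    def row(self, label: str) -> PartitionRow:
        for r in self.rows:
            if r.label == label:
                return r
        raise KeyError(label)


def map_sites_to_partitions(
    calls: SiteCallSet, partitions: ExonPartitionTable
) -> list[tuple[SiteCall, str]]:
    """Annotate each call with its partition label (or 'unassigned')."""
    if calls.protein_length != partitions.protein_length:
        raise ValueError(
            "site calls and partition table disagree on protein length "
            f"({calls.protein_length} vs {partitions.protein_length})"
        )
    return [
        (call, partitions.partition_of(call.position) or UNASSIGNED)
        for call in calls.calls
    ]


def partition_rates(
    calls: SiteCallSet,
    partitions: ExonPartitionTable,
    method: str | None = None,
) -> PartitionCounts:
    """Per-partition counts and rates of positive/negative selected sites.

    Calls from different site-calling methods are never merged silently:
    when the call set mixes methods, ``method`` must name the one to use.
    """
    methods = calls.methods()
    if method is None:
        if len(methods) > 1:
            raise ValueError(
                f"call set mixes methods {methods}; pass method= explicitly"
            )
        method = methods[0] if methods else ""
    annotated = [
        (call, label)
        for call, label in map_sites_to_partitions(calls, partitions)
        if call.method == method
    ]
    counts = {label: {"positive": 0, "negative": 0} for label in partitions.labels()}
    unassigned = {"positive": 0, "negative": 0}
    for call, label in annotated:
        (counts[label] if label != UNASSIGNED else unassigned)[call.category] += 1
    rows = tuple(
        PartitionRow(
            label=label,
            length_aa=partitions.length_aa(label),
            n_positive=counts[label]["positive"],
            n_negative=counts[label]["negative"],
        )
        for label in partitions.labels()
    )
    return PartitionCounts(
        rows=rows,
        unassigned_positive=unassigned["positive"],
        unassigned_negative=unassigned["negative"],
        method=method,
    )


# ---------------------------------------------------------------------------
# Two-proportion z test


@dataclass(frozen=True)
class ProportionTestResult:
    z: float
    p_two_tailed: float
    pooled_p: float


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> ProportionTestResult:
    """Pooled two-proportion z test, two-tailed, no continuity correction.

    z = (p1 - p2) / sqrt(p*(1-p*)(1/n1 + 1/n2)) with p* = (x1+x2)/(n1+n2).
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0 or not 0 <= x <= n:
            raise ValueError(f"invalid count/size pair ({x}, {n})")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise DegenerateProportionsError(
            f"pooled proportion {pooled}: zero variance, z undefined"
        )
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (x1 / n1 - x2 / n2) / se
    return ProportionTestResult(
        z=z, p_two_tailed=float(2 * norm.sf(abs(z))), pooled_p=pooled
    )


# ---------------------------------------------------------------------------
# NG86 dN/dS


@dataclass(frozen=True)
class CodonAlignment:
    """Two gap-free coding sequences of equal length, standard genetic code."""

    seq_a: str
    seq_b: str
    table_id: int = 1

    def __post_init__(self) -> None:
        if self.table_id != 1:
            raise ValueError("only genetic code table 1 is supported")
        for name, seq in (("seq_a", self.seq_a), ("seq_b", self.seq_b)):
            if len(seq) % 3 != 0:
                raise ValueError(f"{name}: length {len(seq)} not a multiple of 3")
            bad = set(seq.upper()) - set(NUCLEOTIDES)
            if bad:
                raise ValueError(f"{name}: illegal characters {sorted(bad)!r}")
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("sequences differ in length")
        if len(self.seq_a) == 0:
            raise ValueError("empty codon alignment")
        object.__setattr__(self, "seq_a", self.seq_a.upper())
        object.__setattr__(self, "seq_b", self.seq_b.upper())
        for name, seq in (("seq_a", self.seq_a), ("seq_b", self.seq_b)):
            protein = str(Seq(seq).translate(table=self.table_id))
            if "*" in protein:
                raise ValueError(f"{name}: internal stop codon")

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def codons(self):
        for k in range(0, len(self.seq_a), 3):
            yield self.seq_a[k : k + 3], self.seq_b[k : k + 3]


@dataclass(frozen=True)
class Ng86Result:
    """Nei-Gojobori counts, proportions, corrected distances and omega.

    ``omega`` is None when undefined (dS = 0 or a Jukes-Cantor correction
    diverges); ``flags`` carries the reasons.
    """

    n_sites: float  # N: nonsynonymous sites
    s_sites: float  # S: synonymous sites
    nd: float  # observed nonsynonymous differences
    sd: float  # observed synonymous differences
    pn: float
    ps: float
    dn: float | None
    ds: float | None
    omega: float | None
    flags: tuple[str, ...] = ()


@lru_cache(maxsize=None)
def _site_fractions(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon.

    Each of the nine single-nucleotide neighbours contributes 1/3 site;
    mutations creating a stop codon count as nonsynonymous.
    """
    aa = _AA[codon]
    syn = 0
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            neighbour = codon[:pos] + nt + codon[pos + 1 :]
            if neighbour not in _STOPS and _AA[neighbour] == aa:
                syn += 1
    return syn / 3.0, 3.0 - syn / 3.0


@lru_cache(maxsize=None)
def _diff_fractions(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts between two sense codons.

    Multi-nucleotide differences are averaged over all minimal mutational
    paths; paths whose intermediate codons are stops are excluded. In the
    (rare) event every path is blocked by a stop, all paths are used.
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff_pos):
        current = codon_a
        steps = []
        blocked = False
        for k, pos in enumerate(order):
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in _STOPS and k < len(order) - 1:
                blocked = True  # intermediate stop; endpoints are sense codons
                break
            steps.append((current, nxt))
            current = nxt
        if not blocked:
            paths.append(steps)
    if not paths:  # every path traverses a stop; fall back to all orders
        for order in permutations(diff_pos):
            current = codon_a
            steps = []
            for pos in order:
                nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
                steps.append((current, nxt))
                current = nxt
            paths.append(steps)
    sd = nd = 0.0
    for steps in paths:
        for before, after in steps:
            if _AA.get(before) == _AA.get(after):
                sd += 1
            else:
                nd += 1
    return sd / len(paths), nd / len(paths)


def _jukes_cantor(p: float) -> float | None:
    """d = -(3/4) ln(1 - 4p/3); None when the correction diverges (p >= 3/4)."""
    if p >= 0.75:
        return None
    return -0.75 * math.log(1 - 4.0 * p / 3.0)


def ng86_dnds(aln: CodonAlignment) -> Ng86Result:
    """Nei-Gojobori (1986) dN/dS with Jukes-Cantor multiple-hit correction.

    Site counts are averaged over the two sequences; difference counts
    average over minimal mutation paths (stop-traversing paths excluded).
    """
    s_a = n_a = s_b = n_b = 0.0
    sd = nd = 0.0
    for ca, cb in aln.codons():
        fa = _site_fractions(ca)
        fb = _site_fractions(cb)
        s_a += fa[0]
        n_a += fa[1]
        s_b += fb[0]
        n_b += fb[1]
        d = _diff_fractions(ca, cb)
        sd += d[0]
        nd += d[1]
    s_sites = (s_a + s_b) / 2.0
    n_sites = (n_a + n_b) / 2.0
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ds = _jukes_cantor(ps)
    dn = _jukes_cantor(pn)
    flags = []
    if ds is None:
        flags.append("ds_correction_diverges")
    if dn is None:
        flags.append("dn_correction_diverges")
    omega: float | None = None
    if dn is not None and ds is not None:
        if ds == 0.0:
            flags.append("ds_zero")
        else:
            omega = dn / ds
    return Ng86Result(
        n_sites=n_sites,
        s_sites=s_sites,
        nd=nd,
        sd=sd,
        pn=pn,
        ps=ps,
        dn=dn,
        ds=ds,
        omega=omega,
        flags=tuple(flags),
    )


def read_codon_alignment(path) -> CodonAlignment:
    """Read a two-record CDS FASTA (gap-free, equal length) as a CodonAlignment."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError(f"{path}: expected exactly 2 records, got {len(records)}")
    return CodonAlignment(str(records[0].seq), str(records[1].seq))


def write_partition_report(
    counts: PartitionCounts,
    path,
    test: ProportionTestResult | None = None,
    provenance: dict | None = None,
) -> None:
    """Partition-rate TSV with the optional z test in the commented header."""
    with open(path, "w") as fh:
        for k, v in (provenance or {}).items():
            fh.write(f"# {k}: {v}\n")
        fh.write(f"# method: {counts.method}\n")
        if test is not None:
            fh.write(
                f"# two_proportion_z: {test.z:.3f} p_two_tailed: "
                f"{test.p_two_tailed:.2f} pooled_p: {test.pooled_p:.4f}\n"
            )
        fh.write(
            "partition\tlength_aa\tn_positive\tn_negative\t"
            "rate_positive\trate_negative\n"
        )
        for r in counts.rows:
            fh.write(
                f"{r.label}\t{r.length_aa}\t{r.n_positive}\t{r.n_negative}\t"
                f"{r.rate_positive:.1f}\t{r.rate_negative:.1f}\n"
            )
        fh.write(
            f"{UNASSIGNED}\t0\t{counts.unassigned_positive}\t"
            f"{counts.unassigned_negative}\t\t\n"
        )
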