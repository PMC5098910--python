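"""Rule-based ortholog triage from per-domain profile-HMM search hits.

Candidate family members are called from the results of searching a protein
database with three domain profiles — a minigluzincin protease domain, a
C2C2 zinc finger and an HMG box.  The decision rules:

1. a hit is significant iff its full-sequence E-value is strictly below the
   threshold (default 1e-5);
2. for genes with several predicted isoforms, only the longest isoform is
   kept (ties broken by lexicographically smallest id);
3. for species sampled as multiple strains, only one strain is kept — the one
   contributing the longest protein;
4. exact or reciprocal-search duplicates are collapsed to one representative
   (longest, then lexicographically smallest id);
5. a protein with significant hits to all three domains is a *full* family
   member; protease + zinc finger but not all three is *partial*; anything
   else is *none*.

The searches themselves (hmmsearch, reciprocal BLAST) are external; this
module consumes their tabular output.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import networkx as nx

DOMAIN_QUERIES = ("protease", "zinc_finger", "hmg_box")


@dataclass(frozen=True)
class DomainHit:
    """One (protein, domain-query) row from a search hit table."""

    protein_id: str
    domain: str
    evalue: float
    species: str | None = None
    strain: str | None = None
    gene: str | None = None
    length: int | None = None

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise ValueError(f"E-value must be positive, got {self.evalue}")


@dataclass(frozen=True)
class OrthologCall:
    """Family-membership status of one protein after triage."""

    protein_id: str
    species: str | None
    domains: frozenset[str]
    status: Literal["full", "partial", "none"]
    length: int | None = None


def parse_hit_table(path: str | Path,
                    dialect: Literal["hmmer3-domtbl", "tsv"] = "tsv"
                    ) -> list[DomainHit]:
    """Parse a hit table into :class:`DomainHit` rows.

    ``hmmer3-domtbl``: HMMER3 ``--domtblout`` output; the target name, target
    length, query name, and full-sequence independent E-value columns are
    used; one hit is kept per (target, query) pair (the E-value is identical
    across that pair's domain rows).  ``tsv``: tab-separated columns
    protein, species, strain, gene, length, domain, evalue; empty fields mean
    "not recorded"; '#' lines are comments in both dialects.
    """
    path = Path(path)
    hits: list[DomainHit] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            try:
                if dialect == "hmmer3-domtbl":
                    f = line.split()
                    if len(f) < 13:
                        raise ValueError("fewer than 13 whitespace-separated fields")
                    key = (f[0], f[3])
                    if key in seen:
                        continue
                    seen.add(key)
                    hits.append(DomainHit(protein_id=f[0], domain=f[3],
                                          evalue=float(f[6]),
                                          length=int(f[2])))
                elif dialect == "tsv":
                    f = line.rstrip("\n").split("\t")
                    if len(f) != 7:
                        raise ValueError(f"expected 7 tab-separated fields, got {len(f)}")
                    protein, species, strain, gene, length, domain, evalue = f
                    hits.append(DomainHit(
                        protein_id=protein,
                        species=species or None,
                        strain=strain or None,
                        gene=gene or None,
                        length=int(length) if length else None,
                        domain=domain,
                        evalue=float(evalue),
                    ))
                else:
                    raise ValueError(f"unknown dialect {dialect!r}")
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: malformed row ({err})")
    return hits


def write_hit_table(hits: Iterable[DomainHit], path: str | Path) -> None:
    """Write hits in the simple TSV dialect (round-trips with the parser)."""
    with open(path, "w") as fh:
        fh.write("# protein\tspecies\tstrain\tgene\tlength\tdomain\tevalue\n")
        for h in hits:
            fh.write("\t".join([
                h.protein_id, h.species or "", h.strain or "", h.gene or "",
                "" if h.length is None else str(h.length),
                h.domain, f"{h.evalue:.6g}",
            ]) + "\n")


def filter_significant(hits: Iterable[DomainHit],
                       threshold: float = 1e-5) -> list[DomainHit]:
    """Keep hits with E-value strictly smaller than the threshold.

    The inequality is strict: a hit at exactly the threshold is removed.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return [h for h in hits if h.evalue < threshold]


def _longest_then_lex(candidates: Sequence[tuple[int, str]]) -> str:
    """Pick the id with the greatest length, ties by smallest id."""
    return min(candidates, key=lambda t: (-t[0], t[1]))[1]


@dataclass
class _ProteinInfo:
    domains: set[str] = field(default_factory=set)
    species: str | None = None
    strain: str | None = None
    gene: str | None = None
    length: int | None = None


def call_orthologs(hits: Iterable[DomainHit], *,
                   isoform_delimiter: str = "-",
                   required_domains: Sequence[str] = DOMAIN_QUERIES
                   ) -> list[OrthologCall]:
    """Assign full/partial/none status per protein after deduplication.

    ``hits`` should already be significance-filtered.  Isoforms are grouped
    by gene tag where present, else by the protein-id root before
    ``isoform_delimiter`` (UniProt style, e.g. ``P12345-2``); the longest
    isoform per group survives.  Per species, a single strain is kept: the
    one contributing the longest protein (untagged entries are unaffected).
    """
    protease, zinc, hmg = required_domains
    info: dict[str, _ProteinInfo] = defaultdict(_ProteinInfo)
    for h in hits:
        p = info[h.protein_id]
        p.domains.add(h.domain)
        p.species = p.species or h.species
        p.strain = p.strain or h.strain
        p.gene = p.gene or h.gene
        if h.length is not None:
            p.length = h.length if p.length is None else max(p.length, h.length)

    def plen(pid: str) -> int:
        L = info[pid].length
        return -1 if L is None else L

    # longest isoform per gene group
    groups: dict[str, list[str]] = defaultdict(list)
    for pid, p in info.items():
        key = p.gene or pid.split(isoform_delimiter, 1)[0]
        groups[key].append(pid)
    survivors = {_longest_then_lex([(plen(pid), pid) for pid in pids])
                 for pids in groups.values()}

    # one strain per species: the strain holding the longest surviving protein
    by_species: dict[str, list[str]] = defaultdict(list)
    for pid in survivors:
        p = info[pid]
        if p.species is not None and p.strain is not None:
            by_species[p.species].append(pid)
    for species, pids in by_species.items():
        strains = {info[pid].strain for pid in pids}
        if len(strains) <= 1:
            continue
        winner_pid = _longest_then_lex([(plen(pid), pid) for pid in pids])
        winner_strain = info[winner_pid].strain
        survivors -= {pid for pid in pids if info[pid].strain != winner_strain}

    calls: list[OrthologCall] = []
    for pid in sorted(survivors):
        p = info[pid]
        if {protease, zinc, hmg} <= p.domains:
            status = "full"
        elif {protease, zinc} <= p.domains:
            status = "partial"
        else:
            status = "none"
        calls.append(OrthologCall(pid, p.species, frozenset(p.domains),
                                  status, p.length))
    return calls


def dedup_identical(calls: Sequence[OrthologCall],
                    identity_pairs: Iterable[tuple[str, str]]
                    ) -> list[OrthologCall]:
    """Collapse identity-related proteins to one representative each.

    ``identity_pairs`` is the edge list of an identity relation (e.g. from an
    all-vs-all reciprocal search, or exact-sequence equality); its connected
    components are each reduced to the longest member, ties by smallest id.
    """
    by_id = {c.protein_id: c for c in calls}
    g = nx.Graph()
    g.add_nodes_from(by_id)
    for a, b in identity_pairs:
        for x in (a, b):
            if x not in by_id:
                raise KeyError(f"identity pair references unknown protein {x!r}")
        g.add_edge(a, b)
    kept: list[OrthologCall] = []
    for comp in nx.connected_components(g):
        rep = _longest_then_lex([
            (-1 if by_id[p].length is None else by_id[p].length, p)
            for p in comp
        ])
        kept.append(by_id[rep])
    return sorted(kept, key=lambda c: c.protein_id)


def status_counts(calls: Iterable[OrthologCall]) -> dict[str, int]:
    out = {"full": 0, "partial": 0, "none": 0}
    for c in calls:
        out[c.status] += 1
    return out
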