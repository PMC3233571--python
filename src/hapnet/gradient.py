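"""Diversity-gradient tabulations over the haplotype network.

For a chosen set of core haplotypes, every haplotype falls into one of three
mutational-distance classes — ``core`` (distance 0 to the nearest core),
``N1`` (distance 1) and ``N2`` (distance ≥ 2) — and may additionally be
*unique* (``Nu``): observed in exactly one geographic region. Tabulating
haplotype and individual counts of these classes per region and
domestic/wild status yields the regional diversity table; regions whose
derived (N1+N2) and unique richness peaks are candidate domestication
centres, ranked by :func:`rank_centers` with an explicit weighted score.

Counting conventions (the published tables state none):

* ``Nu`` defaults to region-private over *all* individuals regardless of
  status (``unique_scope="region"``); ``"region-status"`` restricts privacy
  to the (region, status) cell.
* In the haplogroup sharing table a haplotype counts toward a status column
  if at least one member has that status, so shared haplotypes appear in
  both columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .alignment_io import REGIONS, STATUSES, HaplotypeTable
from .mj_network import HaplotypeGraph
from .subgroups import _dist_to_set

__all__ = [
    "RegionalDiversityRow",
    "HaplogroupSharingRow",
    "CenterRanking",
    "classify_by_core_distance",
    "unique_haplotypes",
    "regional_table",
    "sharing_table",
    "rank_centers",
    "write_table1",
    "write_table2",
    "write_ranking",
]


@dataclass(frozen=True)
class RegionalDiversityRow:
    """One (region, status) row: haplotype and individual counts per class.

    ``no_sample`` marks cells with no individuals (rendered as a short line
    in text output). ``n_unreachable`` counts haplotypes disconnected from
    every core, which are reported within N2.
    """

    region: str
    status: str
    nc_hap: int
    nc_ind: int
    n1_hap: int
    n1_ind: int
    n2_hap: int
    n2_ind: int
    nu_hap: int
    nu_ind: int
    no_sample: bool = False
    n_unreachable: int = 0


@dataclass(frozen=True)
class HaplogroupSharingRow:
    haplogroup: str
    n_hap_domestic: int
    n_hap_wild: int
    n_ind_domestic: int
    n_ind_wild: int
    regions: frozenset[str]


@dataclass(frozen=True)
class CenterRanking:
    """Regions ordered by diversity score (descending; ties alphabetical)."""

    ranking: tuple[tuple[str, float], ...]
    weights: tuple[float, float, float]

    def top(self, k: int) -> list[str]:
        return [r for r, _s in self.ranking[:k]]


def classify_by_core_distance(
    graph: HaplotypeGraph,
    cores: Iterable[str],
    haplotype_id: str,
) -> str:
    """``core`` / ``N1`` / ``N2`` by network distance to the nearest core.

    Haplotypes unreachable from every core classify as ``N2`` (callers may
    flag them separately).
    """
    core_ids = set(cores)
    if not core_ids:
        raise ValueError("core set is empty")
    if haplotype_id not in graph.graph:
        raise KeyError(f"haplotype {haplotype_id!r} not in network")
    d = _dist_to_set(graph, core_ids).get(haplotype_id, float("inf"))
    if d == 0:
        return "core"
    if d <= 1:
        return "N1"
    return "N2"


def unique_haplotypes(
    table: HaplotypeTable,
    scope: str = "region",
) -> dict:
    """Region-private haplotypes.

    With ``scope="region"`` (default): haplotype → unique to region *r* iff
    all its members, any status, are from *r*; returns region → set of ids.
    With ``scope="region-status"``: privacy per (region, status) cell;
    returns (region, status) → set of ids.
    """
    if not table.haplotypes:
        raise ValueError("empty haplotype table")
    if scope == "region":
        out: dict[str, set[str]] = {}
        for hap in table.haplotype_ids:
            regs = table.regions_of(hap)
            if len(regs) == 1:
                out.setdefault(next(iter(regs)), set()).add(hap)
        return out
    if scope == "region-status":
        out2: dict[tuple[str, str], set[str]] = {}
        for hap in table.haplotype_ids:
            cells = {
                (r, s) for (h, r, s), n in table.counts.items() if h == hap and n > 0
            }
            if len(cells) == 1:
                out2.setdefault(next(iter(cells)), set()).add(hap)
        return out2
    raise ValueError("scope must be 'region' or 'region-status'")


def regional_table(
    table: HaplotypeTable,
    graph: HaplotypeGraph,
    cores: Iterable[str],
    unique_scope: str = "region",
) -> list[RegionalDiversityRow]:
    """Per-(region, status) core / derived / unique tabulation.

    ``table`` is normally restricted to one subgroup beforehand; classes are
    computed against the global core set via network distance. Cores absent
    from a region simply contribute zero there.
    """
    core_ids = set(cores)
    if not core_ids:
        raise ValueError("core set is empty")
    dist = _dist_to_set(graph, core_ids)
    cls: dict[str, str] = {}
    unreachable: set[str] = set()
    for hap in table.haplotype_ids:
        d = dist.get(hap, float("inf"))
        if d == 0:
            cls[hap] = "core"
        elif d <= 1:
            cls[hap] = "N1"
        else:
            cls[hap] = "N2"
            if d == float("inf"):
                unreachable.add(hap)
    uniq = unique_haplotypes(table, scope=unique_scope)
    rows: list[RegionalDiversityRow] = []
    for region in table.regions():
        for status in STATUSES:
            present = [
                hap for hap in table.haplotype_ids
                if table.count(hap, region, status) > 0
            ]
            if not present:
                rows.append(
                    RegionalDiversityRow(
                        region=region, status=status,
                        nc_hap=0, nc_ind=0, n1_hap=0, n1_ind=0,
                        n2_hap=0, n2_ind=0, nu_hap=0, nu_ind=0,
                        no_sample=True,
                    )
                )
                continue
            agg = {"core": [0, 0], "N1": [0, 0], "N2": [0, 0]}
            for hap in present:
                agg[cls[hap]][0] += 1
                agg[cls[hap]][1] += table.count(hap, region, status)
            if unique_scope == "region":
                u_set = uniq.get(region, set())
            else:
                u_set = uniq.get((region, status), set())
            u_present = [h for h in present if h in u_set]
            rows.append(
                RegionalDiversityRow(
                    region=region, status=status,
                    nc_hap=agg["core"][0], nc_ind=agg["core"][1],
                    n1_hap=agg["N1"][0], n1_ind=agg["N1"][1],
                    n2_hap=agg["N2"][0], n2_ind=agg["N2"][1],
                    nu_hap=len(u_present),
                    nu_ind=sum(table.count(h, region, status) for h in u_present),
                    n_unreachable=len(set(present) & unreachable),
                )
            )
    return rows


def sharing_table(
    table: HaplotypeTable,
    partition: Mapping[str, str],
) -> list[HaplogroupSharingRow]:
    """Per-haplogroup domestic/wild haplotype and individual counts.

    ``partition`` must label every haplotype. A haplotype counts toward a
    status column when at least one of its members carries that status.
    """
    missing = [h for h in table.haplotype_ids if h not in partition]
    if missing:
        raise ValueError(f"haplotype(s) missing a haplogroup label: {missing[:5]}")
    rows: list[HaplogroupSharingRow] = []
    for label in sorted(set(partition[h] for h in table.haplotype_ids)):
        haps = [h for h in table.haplotype_ids if partition[h] == label]
        n_hap_dom = sum(1 for h in haps if "domestic" in table.statuses_of(h))
        n_hap_wild = sum(1 for h in haps if "wild" in table.statuses_of(h))
        n_ind_dom = sum(table.total_count(h, "domestic") for h in haps)
        n_ind_wild = sum(table.total_count(h, "wild") for h in haps)
        regions = frozenset().union(*(table.regions_of(h) for h in haps))
        rows.append(
            HaplogroupSharingRow(
                haplogroup=label,
                n_hap_domestic=n_hap_dom,
                n_hap_wild=n_hap_wild,
                n_ind_domestic=n_ind_dom,
                n_ind_wild=n_ind_wild,
                regions=regions,
            )
        )
    return rows


def rank_centers(
    rows: Sequence[RegionalDiversityRow],
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> CenterRanking:
    """Rank regions by weighted derived + unique haplotype richness.

    score(region) = Σ_status w1·N1 + w2·N2 + w3·Nu (haplotype counts).
    Descending; ties broken alphabetically by region code.
    """
    if not rows:
        raise ValueError("no rows to rank")
    if any(w < 0 for w in weights):
        raise ValueError("weights must be nonnegative")
    w1, w2, w3 = weights
    scores: dict[str, float] = {}
    for row in rows:
        scores.setdefault(row.region, 0.0)
        scores[row.region] += w1 * row.n1_hap + w2 * row.n2_hap + w3 * row.nu_hap
    if all(s == 0 for s in scores.values()):
        warnings.warn("degenerate input: all center scores are zero")
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return CenterRanking(ranking=tuple(ordered), weights=(w1, w2, w3))


# ---------------------------------------------------------------------------
# text output (the published tables' layout, '-' short line for empty cells)

_DASH = "-"


def write_table1(rows: Sequence[HaplogroupSharingRow], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "haplogroup\tn_hap_domestic\tn_hap_wild\t"
            "n_ind_domestic\tn_ind_wild\tregions\n"
        )
        for r in rows:
            hd = r.n_hap_domestic or _DASH
            hw = r.n_hap_wild or _DASH
            fh.write(
                f"{r.haplogroup}\t{hd}\t{hw}\t"
                f"{r.n_ind_domestic or _DASH}\t{r.n_ind_wild or _DASH}\t"
                f"{','.join(sorted(r.regions))}\n"
            )


def write_table2(rows: Sequence[RegionalDiversityRow], path) -> None:
    def cell(h: int, i: int) -> str:
        return f"{h} ({i})" if h else "0"

    with open(path, "w") as fh:
        fh.write("region\tstatus\tNc\tN1\tN2\tNu\n")
        for r in rows:
            if r.no_sample:
                fh.write(f"{r.region}\t{r.status}\t{_DASH}\t{_DASH}\t{_DASH}\t{_DASH}\n")
            else:
                fh.write(
                    f"{r.region}\t{r.status}\t"
                    f"{cell(r.nc_hap, r.nc_ind)}\t{cell(r.n1_hap, r.n1_ind)}\t"
                    f"{cell(r.n2_hap, r.n2_ind)}\t{cell(r.nu_hap, r.nu_ind)}\n"
                )


def write_ranking(ranking: CenterRanking, path) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tregion\tscore\n")
        for i, (region, score) in enumerate(ranking.ranking, start=1):
            fh.write(f"{i}\t{region}\t{score:g}\n")
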