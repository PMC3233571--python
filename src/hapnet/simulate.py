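"""Synthetic mtDNA control-region datasets with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, without a full coalescent:

* a uniform-random root sequence of ``seq_length`` (default 431) columns;
* one *wild founder* per region, ``Poisson(theta_wild)`` mutations from the
  root — regional wild pools are therefore several steps apart;
* wild samples: the regional founder plus ``Poisson(1)``-mutation
  satellites;
* each designated *centre* region draws a domestic founder from its own
  wild pool, and domestic samples are ``Poisson(expansion_lambda)``-mutation
  derivatives of that founder — a star-like post-domestication expansion by
  construction;
* each domestic sample is relocated to a uniformly chosen other region with
  probability ``migration_rate``;
* optionally a deep divergent lineage (founder ``extra_mutations`` steps
  from a regional wild founder, plus ``Poisson(1)`` satellites) is planted,
  emulating an isolated highland clade.

Mutation is finite-sites: each of ``k`` distinct columns flips to a uniform
different base, so back-mutation/homoplasy is possible, as on a real 431 bp
segment. A single :class:`numpy.random.Generator` seeded from ``seed``
drives everything; identical parameters give byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .alignment_io import REGIONS, AlignedSeqMatrix, SampleRecord

__all__ = [
    "SimulationParams",
    "SyntheticTruth",
    "SyntheticDataset",
    "mutate",
    "simulate",
    "as_matrix",
    "write_dataset",
]

_BASES = np.array(list("ACGT"))

DEFAULT_CENTERS = ("Tibet", "SEA", "MDYZ")


@dataclass(frozen=True)
class SimulationParams:
    """Generator parameters. Defaults describe a 10-region world with the
    three inferred mainland centres and a modest desk-scale sample."""

    seed: int
    n_regions: int = 10
    center_regions: tuple[str, ...] = DEFAULT_CENTERS
    seq_length: int = 431
    theta_wild: float = 5.0
    n_wild_per_region: int = 10
    n_domestic_per_center: int = 60
    expansion_lambda: float = 1.0
    migration_rate: float = 0.01
    divergent_lineage: tuple[str, int] | None = None
    n_divergent: int = 15

    @property
    def regions(self) -> tuple[str, ...]:
        if self.n_regions > len(REGIONS):
            raise ValueError(f"n_regions must be <= {len(REGIONS)}")
        return REGIONS[: self.n_regions]

    def validate(self) -> None:
        regs = self.regions
        for c in self.center_regions:
            if c not in regs:
                raise ValueError(f"center region {c!r} not among regions {regs}")
        if self.divergent_lineage is not None:
            region, extra = self.divergent_lineage
            if region not in regs:
                raise ValueError(f"divergent-lineage region {region!r} not in regions")
            if extra < 0 or extra > self.seq_length:
                raise ValueError("divergent extra_mutations out of range")
        if not (0.0 <= self.migration_rate <= 1.0):
            raise ValueError("migration_rate must be in [0, 1]")
        if self.seq_length < 1:
            raise ValueError("seq_length must be >= 1")
        if min(self.n_wild_per_region, self.n_domestic_per_center,
               self.n_divergent, self.n_regions) < 0:
            raise ValueError("counts must be nonnegative")
        if self.theta_wild < 0 or self.expansion_lambda < 0:
            raise ValueError("mutation-rate parameters must be nonnegative")


@dataclass
class SyntheticTruth:
    """Ground truth: true centres, founder sequences, and per-sample origin."""

    centers: tuple[str, ...]
    founders: dict[str, str]          # center/divergent label -> founder sequence
    root: str
    samples: dict[str, dict]          # sample_id -> {origin, home_region, region,
                                      #               status, n_mutations}
    params: SimulationParams

    def divergent_samples(self) -> set[str]:
        return {s for s, rec in self.samples.items() if rec["origin"] == "divergent"}


@dataclass
class SyntheticDataset:
    records: list[tuple[str, str]]        # (sample_id, sequence), aligned
    annotations: list[SampleRecord]
    truth: SyntheticTruth


def mutate(seq: str, k: int, rng: np.random.Generator) -> str:
    """Change exactly ``k`` distinct columns, each to a uniform different base."""
    if k > len(seq):
        raise ValueError(f"cannot mutate {k} columns of a length-{len(seq)} sequence")
    if k == 0:
        return seq
    cols = rng.choice(len(seq), size=k, replace=False)
    out = list(seq)
    for c in cols:
        alternatives = [b for b in "ACGT" if b != out[c]]
        out[c] = alternatives[rng.integers(3)]
    return "".join(out)


def _poisson_capped(rng: np.random.Generator, lam: float, cap: int) -> int:
    return min(int(rng.poisson(lam)), cap)


def simulate(params: SimulationParams) -> SyntheticDataset:
    """Generate an aligned dataset plus annotations and ground truth."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    L = params.seq_length
    regs = params.regions
    root = "".join(rng.choice(_BASES, size=L))

    wild_founders: dict[str, str] = {}
    for region in regs:
        wild_founders[region] = mutate(root, _poisson_capped(rng, params.theta_wild, L), rng)

    records: list[tuple[str, str]] = []
    annotations: list[SampleRecord] = []
    samples: dict[str, dict] = {}
    counter = 0

    def emit(seq, region, status, origin, home, n_mut, breed="sim"):
        nonlocal counter
        counter += 1
        sid = f"S{counter:05d}"
        records.append((sid, seq))
        annotations.append(SampleRecord(sample_id=sid, region=region,
                                        status=status, breed=breed))
        samples[sid] = {
            "origin": origin, "home_region": home, "region": region,
            "status": status, "n_mutations": int(n_mut),
        }
        return sid, seq

    # wild pools (first wild sample of each region is the founder itself,
    # so every pool is guaranteed nonempty around its founder)
    wild_pool: dict[str, list[str]] = {r: [] for r in regs}
    for region in regs:
        for i in range(params.n_wild_per_region):
            k = 0 if i == 0 else _poisson_capped(rng, 1.0, L)
            seq = wild_founders[region] if k == 0 else mutate(wild_founders[region], k, rng)
            emit(seq, region, "wild", "wild", region, k)
            wild_pool[region].append(seq)

    # domestication centres: founder drawn from the centre's own wild pool
    founders: dict[str, str] = {}
    for center in params.center_regions:
        pool = wild_pool[center]
        founder = pool[rng.integers(len(pool))] if pool else wild_founders[center]
        founders[center] = founder
        for _ in range(params.n_domestic_per_center):
            k = _poisson_capped(rng, params.expansion_lambda, L)
            seq = founder if k == 0 else mutate(founder, k, rng)
            region = center
            if params.migration_rate > 0 and rng.random() < params.migration_rate:
                others = [r for r in regs if r != center]
                region = others[rng.integers(len(others))]
            emit(seq, region, "domestic", center, center, k)

    # optional deep divergent lineage (domestic, stays in its home region)
    if params.divergent_lineage is not None:
        region, extra = params.divergent_lineage
        div_founder = mutate(wild_founders[region], extra, rng)
        founders["divergent"] = div_founder
        for i in range(params.n_divergent):
            k = 0 if i == 0 else _poisson_capped(rng, 1.0, L)
            seq = div_founder if k == 0 else mutate(div_founder, k, rng)
            emit(seq, region, "domestic", "divergent", region, k)

    truth = SyntheticTruth(
        centers=tuple(params.center_regions),
        founders=founders,
        root=root,
        samples=samples,
        params=params,
    )
    return SyntheticDataset(records=records, annotations=annotations, truth=truth)


def as_matrix(dataset: SyntheticDataset) -> AlignedSeqMatrix:
    """View the (gap-free) synthetic alignment as an AlignedSeqMatrix,
    bypassing the FASTA round trip."""
    L = len(dataset.records[0][1]) if dataset.records else 0
    return AlignedSeqMatrix(
        sample_ids=tuple(sid for sid, _ in dataset.records),
        residues=tuple(seq for _, seq in dataset.records),
        source_columns=tuple(range(L)),
    )


def write_dataset(dataset: SyntheticDataset, directory: str | Path) -> dict[str, Path]:
    """Write synthetic.fasta, synthetic.tsv and truth.json; the FASTA/TSV
    round-trip losslessly through the alignment readers."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fasta = directory / "synthetic.fasta"
    tsv = directory / "synthetic.tsv"
    truth_path = directory / "truth.json"
    with open(fasta, "w") as fh:
        for sid, seq in dataset.records:
            fh.write(f">{sid}\n{seq}\n")
    with open(tsv, "w") as fh:
        fh.write("sample_id\tregion\tstatus\tbreed\n")
        for rec in dataset.annotations:
            fh.write(f"{rec.sample_id}\t{rec.region}\t{rec.status}\t{rec.breed}\n")
    truth = dataset.truth
    payload = {
        "centers": list(truth.centers),
        "founders": truth.founders,
        "root": truth.root,
        "samples": truth.samples,
        "params": asdict(truth.params),
    }
    with open(truth_path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return {"fasta": fasta, "tsv": tsv, "truth": truth_path}
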