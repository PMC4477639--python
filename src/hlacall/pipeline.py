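"""End-to-end sample processing: FASTQ -> mappings -> profiles -> genotype calls.

The library entry points here are what the command-line interface wraps:
:func:`map_records` turns read records into per-allele mapping lists,
:func:`call_sample` runs filtering and pair scoring for every locus, and
:func:`write_results_csv` / :func:`write_qc_tables` emit the machine-readable
outputs (one results row per sample x locus; QC tables as TSV).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from hlacall.calling import (
    DEFAULT_CENTRAL_RATIO_THRESHOLD,
    DEFAULT_LOW_COV_AUC_THRESHOLD,
    DEFAULT_READ_COUNT_THRESHOLD,
    GenotypeCall,
    Weights,
    call_genotype,
    prefilter_candidates,
)
from hlacall.mapping import (
    DEFAULT_MIN_TRUNC_LEN,
    Mapping,
    MappingIndex,
    reduce_start_points,
)
from hlacall.reference import AlleleReference

logger = logging.getLogger("hlacall")


@dataclass
class RunConfig:
    """Tunable thresholds of a calling run (defaults are the recommended ones)."""

    min_trunc_len: int = DEFAULT_MIN_TRUNC_LEN
    read_len: int = 100
    central_ratio_threshold: float = DEFAULT_CENTRAL_RATIO_THRESHOLD
    low_cov_auc_threshold: float = DEFAULT_LOW_COV_AUC_THRESHOLD
    read_count_threshold: int = DEFAULT_READ_COUNT_THRESHOLD
    weights: Weights = field(default_factory=Weights)
    force_include: dict[str, list[str]] = field(default_factory=dict)  # locus -> alleles
    force_exclude: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.min_trunc_len < 1 or self.read_len < self.min_trunc_len:
            raise ValueError("need 1 <= min_trunc_len <= read_len")
        if self.central_ratio_threshold < 0 or self.low_cov_auc_threshold <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "weights" in d and not isinstance(d["weights"], Weights):
            d["weights"] = Weights(**d["weights"])
        return cls(**d)


def read_fastq_pairs(
    fastq1: str | Path, fastq2: str | Path
) -> Iterator[tuple[str, int, str]]:
    """Yield (read_id, mate, sequence) from two FASTQ(.gz) files.

    The read id is the header token before the first space (Casava 1.8 style:
    mates share it). Files are streamed in lockstep, so order defines pairing.
    """

    def _records(path):
        p = str(path)
        opener = gzip.open if p.endswith(".gz") else open
        with opener(p, "rt") as fh:
            while True:
                header = fh.readline()
                if not header:
                    return
                seq = fh.readline().strip().upper()
                plus = fh.readline()
                fh.readline()
                if not header.startswith("@") or not plus.startswith("+"):
                    raise ValueError(f"{p}: malformed FASTQ record near {header!r}")
                yield header[1:].split()[0], seq

    for mate, path in ((1, fastq1), (2, fastq2)):
        for rid, seq in _records(path):
            yield rid, mate, seq


@dataclass
class MappingStore:
    """All mappings of a sample grouped per allele, plus run counters."""

    by_allele: dict[str, list[Mapping]] = field(default_factory=dict)
    n_reads: int = 0
    n_mapped_reads: int = 0

    def add(self, mappings: list[Mapping]) -> None:
        self.n_reads += 1
        if mappings:
            self.n_mapped_reads += 1
        for m in mappings:
            self.by_allele.setdefault(m.allele, []).append(m)


def map_records(
    records: Iterable[tuple[str, int, str]], index: MappingIndex
) -> MappingStore:
    """Map every read record against the index; reads shorter than the
    truncation minimum or containing only non-indexable sequence simply do
    not map."""
    store = MappingStore()
    mtl = index.min_trunc_len
    for rid, mate, seq in records:
        if len(seq) < mtl:
            store.add([])
            continue
        store.add(index.query(seq, rid, mate))
    return store


def call_sample(
    reference: AlleleReference,
    index: MappingIndex,
    store: MappingStore,
    config: RunConfig = RunConfig(),
    loci: Iterable[str] | None = None,
) -> dict[str, GenotypeCall]:
    """Run pre-filtering and genotype calling for every locus of the reference."""
    calls: dict[str, GenotypeCall] = {}
    for locus in loci if loci is not None else reference.loci:
        profiles = {}
        for allele in reference.by_locus(locus):
            profiles[str(allele.name)] = reduce_start_points(
                store.by_allele.get(str(allele.name), ()),
                allele,
                read_len=config.read_len,
                min_trunc_len=config.min_trunc_len,
            )
        sample_auc = max((p.auc for p in profiles.values()), default=0.0)
        pre = prefilter_candidates(
            profiles,
            low_cov_mode=sample_auc < config.low_cov_auc_threshold,
            central_ratio_threshold=config.central_ratio_threshold,
            read_len=config.read_len,
            force_include=config.force_include.get(locus, ()),
            force_exclude=config.force_exclude.get(locus, ()),
        )
        call = call_genotype(
            locus,
            profiles,
            pre.candidates,
            store.by_allele,
            weights=config.weights,
            total_reads=store.n_reads,
            low_cov_auc_threshold=config.low_cov_auc_threshold,
            read_count_threshold=config.read_count_threshold,
        )
        call.qc = pre.qc
        call.review = pre.review
        calls[locus] = call
        logger.info(
            "locus=%s reads_in=%d mapped=%d profiled=%d candidates=%d pairs=%d best=%s",
            locus,
            store.n_reads,
            store.n_mapped_reads,
            len(profiles),
            len(pre.candidates),
            len(call.ranked),
            call.best,
        )
    return calls


def run_call(
    fastq1: str | Path,
    fastq2: str | Path,
    reference: AlleleReference,
    config: RunConfig = RunConfig(),
    sample: str = "sample",
) -> tuple[dict[str, GenotypeCall], MappingStore]:
    """Full single-sample run from FASTQ inputs."""
    index = MappingIndex(reference, config.min_trunc_len)
    store = map_records(read_fastq_pairs(fastq1, fastq2), index)
    logger.info(
        "sample=%s reads_in=%d mapped=%d alleles_hit=%d",
        sample,
        store.n_reads,
        store.n_mapped_reads,
        len(store.by_allele),
    )
    return call_sample(reference, index, store, config), store


def results_dataframe(
    calls: dict[str, GenotypeCall], sample: str = "sample"
) -> pd.DataFrame:
    """One row per sample x locus with the best pair, its raw parameters,
    alternatives and flags."""
    rows = []
    for locus, call in calls.items():
        if call.no_call:
            rows.append(
                {
                    "sample": sample,
                    "locus": locus,
                    "allele1": "",
                    "allele2": "",
                    "H": float("nan"),
                    "n_alternatives": 0,
                    "alternatives": "",
                    "asm": float("nan"),
                    "req": float("nan"),
                    "msl": float("nan"),
                    "mppr": float("nan"),
                    "auc": float("nan"),
                    "flags": ";".join(call.flags),
                }
            )
            continue
        best = call.ranked[0]
        rows.append(
            {
                "sample": sample,
                "locus": locus,
                "allele1": best.pair[0],
                "allele2": best.pair[1],
                "H": best.H,
                "n_alternatives": len(call.alternatives),
                "alternatives": ";".join("/".join(p) for p in call.alternatives),
                "asm": best.raw.asm,
                "req": best.raw.req,
                "msl": best.raw.msl,
                "mppr": best.raw.mppr,
                "auc": best.raw.auc,
                "flags": ";".join(call.flags),
            }
        )
    return pd.DataFrame(rows)


def write_results_csv(calls: dict[str, GenotypeCall], path: str | Path, sample: str = "sample") -> None:
    results_dataframe(calls, sample).to_csv(path, index=False)


def write_qc_tables(calls: dict[str, GenotypeCall], out_dir: str | Path, sample: str = "sample") -> None:
    out = Path(out_dir)
    failed_rows = []
    under_rows = []
    for locus, call in calls.items():
        qc = getattr(call, "qc", None)
        if qc is None:
            continue
        failed_rows += [
            {"sample": sample, "locus": locus, "allele": a, "error": e} for a, e in qc.failed
        ]
        under_rows += [
            {"sample": sample, "locus": locus, "allele": a, "uncovered_bases": e}
            for a, e in qc.undercovered
        ]
    pd.DataFrame(
        failed_rows, columns=["sample", "locus", "allele", "error"]
    ).to_csv(out / "qc_failed.tsv", sep="\t", index=False)
    pd.DataFrame(
        under_rows, columns=["sample", "locus", "allele", "uncovered_bases"]
    ).to_csv(out / "qc_undercovered.tsv", sep="\t", index=False)


def write_coverage_profiles(
    reference: AlleleReference,
    index: MappingIndex,
    store: MappingStore,
    alleles: Iterable[str],
    path: str | Path,
    config: RunConfig = RunConfig(),
) -> None:
    """Per-allele observed vs ideal coverage dump (TSV) for plotting."""
    rows = []
    for name in alleles:
        allele = reference.get(name)
        prof = reduce_start_points(
            store.by_allele.get(str(allele.name), ()),
            allele,
            read_len=config.read_len,
            min_trunc_len=config.min_trunc_len,
        )
        for i in range(len(prof.coverage)):
            rows.append(
                {
                    "allele": name,
                    "position": i,
                    "observed": int(prof.coverage[i]),
                    "ideal": int(prof.ideal[i]),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
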