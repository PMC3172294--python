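"""Deterministic synthetic fixtures for the three submission scenarios.

The generator emulates the inputs of the three canonical submission
workflows so tests, docs and the acceptance script never need external
data:

* ``single``   — one marker-gene (16S rRNA-like) sequence with one CD set,
  using the MIMARKS-survey checklist and the water package (a coastal
  seawater isolate survey).
* ``genome``   — a multi-contig draft genome with a single CD set for all
  contigs, using the MIGS bacterial-genome checklist and the sediment
  package.
* ``clonelib`` — a 99-record 16S rRNA clone library partitioned into four
  contiguous subgroups, each with its own CD set (MIMARKS-survey +
  sediment), delivered as a filled CSV template.

Sequences are uniform random nucleotides; CD values come from the bundled
registry's own example strings (guaranteeing checklist validity), with the
subgroup depth varied so the four clone-library CD sets are distinct.
All outputs are a pure function of the seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

from .cd_model import CDElement
from .checklist_model import Registry, load_registry
from .csv_io import export_cd_sets

__all__ = ["FixtureInfo", "generate_fixture", "SCENARIOS"]

SCENARIOS = ("single", "genome", "clonelib")

CLONELIB_RECORDS = 99
CLONELIB_SUBGROUPS = 4

_BYTE_TO_BASE = bytes.maketrans(bytes(range(256)), b"ACGT" * 64)


@dataclass
class FixtureInfo:
    """Ledger of what the generator wrote, for downstream verification."""

    scenario: str
    fasta: Path
    cd_csv: Path
    ids: list[str]
    partition: list[tuple[str, str, str]]  # (label, first_id, last_id)
    cd_sets: list[CDElement]


def _random_residues(rng: random.Random, length: int) -> str:
    return rng.randbytes(length).translate(_BYTE_TO_BASE).decode("ascii")


def _write_fasta(path: Path, records: list[tuple[str, str, str]], wrap: int = 70) -> None:
    with open(path, "w", encoding="ascii", newline="") as fh:
        for rid, desc, residues in records:
            head = rid if not desc else f"{rid} {desc}"
            fh.write(f">{head}\n")
            for i in range(0, len(residues), wrap):
                fh.write(residues[i : i + wrap] + "\n")


def _example_values(registry: Registry, report_type: str, package: str) -> dict[str, str]:
    """Fill every checklist field with the registry's own example value."""
    return {
        p.short_name: p.example
        for p in registry.compose_parameter_set(report_type, package)
    }


def _contiguous_partition(rng: random.Random, n: int, k: int) -> list[int]:
    """Sizes of k non-empty contiguous runs covering n items."""
    cuts = sorted(rng.sample(range(1, n), k - 1))
    bounds = [0, *cuts, n]
    return [bounds[i + 1] - bounds[i] for i in range(k)]


def generate_fixture(
    scenario: str,
    seed: int,
    out_dir: str | Path,
    *,
    registry: Registry | None = None,
    genome_total_size: int = 500_000,
    genome_contigs: int = 25,
) -> FixtureInfo:
    """Write the FASTA + CD CSV for one scenario; deterministic per seed."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    if registry is None:
        registry = load_registry()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed)

    if scenario == "single":
        rid = "isolate16S_001"
        records = [
            (rid, "16S rRNA gene, coastal seawater isolate", _random_residues(rng, rng.randint(1400, 1550)))
        ]
        values = _example_values(registry, "mimarks_s", "water")
        values["investigation_type"] = "mimarks-survey"
        cd_sets = [
            CDElement("mimarks_s", "water", values=values, label="seawater_isolate")
        ]
        partition = [("seawater_isolate", "", "")]

    elif scenario == "genome":
        sizes = _contiguous_partition(rng, genome_total_size, genome_contigs)
        records = [
            (f"contig_{i + 1:04d}", "draft genome contig", _random_residues(rng, size))
            for i, size in enumerate(sizes)
        ]
        values = _example_values(registry, "migs_ba", "sediment")
        values["investigation_type"] = "bacteria_archaea"
        cd_sets = [
            CDElement("migs_ba", "sediment", values=values, label="draft_genome")
        ]
        partition = [("draft_genome", "", "")]

    else:  # clonelib
        records = [
            (
                f"clone_{i + 1:03d}",
                "16S rRNA gene clone",
                _random_residues(rng, rng.randint(750, 900)),
            )
            for i in range(CLONELIB_RECORDS)
        ]
        sizes = _contiguous_partition(rng, CLONELIB_RECORDS, CLONELIB_SUBGROUPS)
        cd_sets = []
        partition = []
        start = 0
        for g, size in enumerate(sizes):
            first = records[start][0]
            last = records[start + size - 1][0]
            values = _example_values(registry, "mimarks_s", "sediment")
            values["investigation_type"] = "mimarks-survey"
            # distinct CD per subgroup: vary sampling depth and date
            values["depth"] = f"{(g + 1) * 5} m"
            values["collection_date"] = f"2010-0{g + 3}-15"
            label = f"subgroup_{g + 1}"
            cd_sets.append(
                CDElement(
                    "mimarks_s",
                    "sediment",
                    values=values,
                    first_sequence_id=first,
                    last_sequence_id=last,
                    label=label,
                )
            )
            partition.append((label, first, last))
            start += size

    fasta = out_dir / f"{scenario}.fasta"
    cd_csv = out_dir / f"{scenario}_cd.csv"
    _write_fasta(fasta, records)
    export_cd_sets(registry, cd_sets, cd_csv)
    return FixtureInfo(
        scenario=scenario,
        fasta=fasta,
        cd_csv=cd_csv,
        ids=[r[0] for r in records],
        partition=partition,
        cd_sets=cd_sets,
    )
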