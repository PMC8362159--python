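"""Plain-text readers and writers for the four breeding-file formats.

* genotype file: one row per individual, ID then one 0/1/2/9 code per Hd
  marker, whitespace separated;
* pedigree file: three columns (ID parent1 parent2), 0 = unknown parent;
* map file: marker ID, chromosome, position in cM;
* phase file: two rows per individual (ID then hap1 alleles / ID then
  hap2 alleles, coded 0/1/9).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .core import GenotypeMatrix, HaplotypePair, MarkerPanel, Pedigree


def read_genotypes(path: str | Path, marker_ids: list[str] | None = None) -> GenotypeMatrix:
    """Read a genotype file; marker IDs default to m1..mN.

    Raises ``ValueError`` with a line number on ragged rows or
    non-integer tokens.
    """
    individuals: list[str] = []
    rows: list[np.ndarray] = []
    width: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            ind, *codes = tokens
            if width is None:
                width = len(codes)
            elif len(codes) != width:
                raise ValueError(
                    f"{path}:{lineno}: expected {width} genotypes, got {len(codes)}"
                )
            try:
                row = np.array([int(c) for c in codes], dtype=np.int8)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer genotype token") from exc
            individuals.append(ind)
            rows.append(row)
    if width is None:
        raise ValueError(f"{path}: empty genotype file")
    if marker_ids is None:
        marker_ids = [f"m{i + 1}" for i in range(width)]
    return GenotypeMatrix(individuals, marker_ids, np.vstack(rows))


def write_genotypes(path: str | Path, geno: GenotypeMatrix) -> None:
    with open(path, "w") as fh:
        for ind in geno.individual_ids:
            fh.write(ind + " " + " ".join(map(str, geno.row(ind))) + "\n")


def read_pedigree(path: str | Path) -> Pedigree:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            ind, p1, p2 = tokens
            records.append(
                (ind, None if p1 == "0" else p1, None if p2 == "0" else p2)
            )
    return Pedigree(records)


def write_pedigree(path: str | Path, ped: Pedigree) -> None:
    with open(path, "w") as fh:
        for ind in ped.topological_order():
            p1, p2 = ped.parents(ind)
            fh.write(f"{ind} {p1 or 0} {p2 or 0}\n")


def read_map(path: str | Path, ld_marker_ids: list[str] | None = None) -> MarkerPanel:
    markers, chroms, positions = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            markers.append(tokens[0])
            chroms.append(tokens[1])
            try:
                positions.append(float(tokens[2]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad position") from exc
    return MarkerPanel(
        markers, np.array(chroms), np.array(positions), ld_marker_ids or []
    )


def write_map(path: str | Path, panel: MarkerPanel) -> None:
    with open(path, "w") as fh:
        for m, c, p in zip(panel.marker_ids, panel.chromosomes, panel.positions_cm):
            fh.write(f"{m} {c} {p:.6f}\n")


def read_marker_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.split()[0] for line in fh if line.split()]


def write_marker_list(path: str | Path, markers: list[str]) -> None:
    with open(path, "w") as fh:
        for m in markers:
            fh.write(m + "\n")


def read_phases(path: str | Path) -> dict[str, HaplotypePair]:
    """Read a phase file (two consecutive rows per individual)."""
    pending: dict[str, np.ndarray] = {}
    phases: dict[str, HaplotypePair] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            ind, *alleles = tokens
            try:
                hap = np.array([int(a) for a in alleles], dtype=np.int8)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer allele") from exc
            if ind in pending:
                phases[ind] = HaplotypePair(pending.pop(ind), hap)
            elif ind in phases:
                raise ValueError(f"{path}:{lineno}: more than two rows for {ind!r}")
            else:
                pending[ind] = hap
    if pending:
        raise ValueError(f"{path}: odd number of rows for {sorted(pending)[:3]}")
    return phases


def write_phases(path: str | Path, phases: dict[str, HaplotypePair]) -> None:
    with open(path, "w") as fh:
        for ind, pair in phases.items():
            fh.write(ind + " " + " ".join(map(str, pair.hap1)) + "\n")
            fh.write(ind + " " + " ".join(map(str, pair.hap2)) + "\n")
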