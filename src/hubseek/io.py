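"""Readers and writers for genotype data.

EIGENSTRAT (unpacked text geno/snp/ind triplet) is the canonical interchange
dialect; VCF import converts on read.  ``.geno`` values follow the convertf
convention — the count of the REFERENCE allele (9 = missing) — while the
in-memory container stores the dosage of the variant/derived allele, so values
are complemented on read and write.  Pseudo-haploid samples use the 0/2 coding
on disk and dosage ∈ {0, 1} in memory.

Ancestral alleles come either from a two-column tab-separated table keyed by
``chrom:pos`` or from the ``AA`` INFO tag of a VCF.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, StructuralError
from .genotypes import MISSING, PolarizedGenotypes

_NUCLEOTIDES = frozenset("ACGT")


def read_genotypes(
    path: str | Path,
    format: str = "eigenstrat",
    *,
    pseudo_haploid: set[str] | None = None,
) -> PolarizedGenotypes:
    """Dispatch to :func:`read_eigenstrat` (``path`` = triplet prefix) or
    :func:`read_vcf`.  Returned dosages are counted against the file's
    reference allele and are *unpolarized*."""
    if format == "eigenstrat":
        return read_eigenstrat(path, pseudo_haploid=pseudo_haploid)
    if format == "vcf":
        return read_vcf(path, pseudo_haploid=pseudo_haploid)
    raise ValueError(f"unknown format {format!r}; expected 'eigenstrat' or 'vcf'")


def read_eigenstrat(
    prefix: str | Path, *, pseudo_haploid: set[str] | None = None
) -> PolarizedGenotypes:
    """Read an unpacked EIGENSTRAT triplet ``prefix.{geno,snp,ind}``."""
    prefix = Path(prefix)
    geno_path = prefix.with_suffix(".geno")
    snp_path = prefix.with_suffix(".snp")
    ind_path = prefix.with_suffix(".ind")
    pseudo_haploid = pseudo_haploid or set()

    samples = _read_ind(ind_path, pseudo_haploid)
    sites = _read_snp(snp_path)

    lines = geno_path.read_text().splitlines()
    if not lines:
        raise StructuralError(f"{geno_path}: empty geno file")
    if len(lines) != len(sites):
        raise StructuralError(
            f"{geno_path}: {len(lines)} genotype rows but {len(sites)} snp records"
        )
    calls = np.empty((len(sites), len(samples)), dtype=np.int8)
    ploidy = samples["ploidy"].to_numpy()
    for i, line in enumerate(lines):
        if len(line) != len(samples):
            raise StructuralError(
                f"{geno_path}, line {i + 1}: {len(line)} genotype characters "
                f"for {len(samples)} individuals"
            )
        try:
            row = np.frombuffer(line.encode(), dtype=np.uint8) - ord("0")
        except ValueError as e:  # pragma: no cover - frombuffer never raises here
            raise ParseError(f"{geno_path}, line {i + 1}: {e}")
        if not np.isin(row, (0, 1, 2, 9)).all():
            raise ParseError(f"{geno_path}, line {i + 1}: invalid genotype character")
        calls[i] = _from_ref_count(row, ploidy, where=f"{geno_path}, line {i + 1}")
    return PolarizedGenotypes(sites=sites, samples=samples, calls=calls)


def _from_ref_count(row: np.ndarray, ploidy: np.ndarray, where: str) -> np.ndarray:
    """Convert reference-allele counts to variant dosage, honouring ploidy."""
    out = np.where(row == 9, MISSING, 2 - row).astype(np.int8)
    haploid = ploidy == 1
    if haploid.any():
        h = row[haploid]
        if (h == 1).any():
            raise ParseError(f"{where}: heterozygous call for a pseudo-haploid sample")
        out[haploid] = np.where(h == 9, MISSING, (h == 0).astype(np.int8))
    return out


def _read_snp(path: Path) -> pd.DataFrame:
    records = []
    for i, line in enumerate(path.read_text().splitlines()):
        parts = line.split()
        if len(parts) < 6:
            raise ParseError(f"{path}, line {i + 1}: expected 6 fields, got {len(parts)}")
        _, chrom, _gpos, pos, ref, alt = parts[:6]
        try:
            pos = int(pos)
        except ValueError:
            raise ParseError(f"{path}, line {i + 1}: non-integer position {parts[3]!r}")
        records.append((chrom, pos, ref, alt))
    return pd.DataFrame(records, columns=["chrom", "pos", "ref", "alt"])


def _read_ind(path: Path, pseudo_haploid: set[str]) -> pd.DataFrame:
    records = []
    for i, line in enumerate(path.read_text().splitlines()):
        parts = line.split()
        if len(parts) != 3:
            raise ParseError(f"{path}, line {i + 1}: expected 3 fields, got {len(parts)}")
        name, _sex, pop = parts
        records.append((name, pop, 1 if name in pseudo_haploid else 2))
    df = pd.DataFrame(records, columns=["id", "population", "ploidy"])
    unknown = pseudo_haploid - set(df["id"])
    if unknown:
        raise StructuralError(f"pseudo-haploid ids not in {path}: {sorted(unknown)}")
    return df


def write_eigenstrat(geno: PolarizedGenotypes, prefix: str | Path) -> None:
    """Write an unpacked EIGENSTRAT triplet (convertf reference-count coding)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    ploidy = geno.samples["ploidy"].to_numpy()
    ref_count = np.where(geno.calls == MISSING, 9, 2 - geno.calls)
    haploid = ploidy == 1
    if haploid.any():
        block = geno.calls[:, haploid]
        ref_count[:, haploid] = np.where(block == MISSING, 9, np.where(block == 1, 0, 2))
    digits = (ref_count.astype(np.uint8) + ord("0")).view("S1")
    with open(prefix.with_suffix(".geno"), "w") as f:
        for row in digits:
            f.write(b"".join(row).decode() + "\n")
    with open(prefix.with_suffix(".snp"), "w") as f:
        for i, s in geno.sites.iterrows():
            f.write(
                f"{s.chrom}_{s.pos}\t{s.chrom}\t0.0\t{s.pos}\t{s.ref}\t{s.alt}\n"
            )
    with open(prefix.with_suffix(".ind"), "w") as f:
        for _, s in geno.samples.iterrows():
            f.write(f"{s.id}\tU\t{s.population}\n")


def read_vcf(
    path: str | Path,
    *,
    pseudo_haploid: set[str] | None = None,
    populations: dict[str, str] | None = None,
) -> PolarizedGenotypes:
    """Read a VCF (v4.x); multiallelic and indel records are dropped with a
    warning count.  ``populations`` maps sample id → population label (defaults
    to the sample id itself)."""
    from cyvcf2 import VCF

    pseudo_haploid = pseudo_haploid or set()
    populations = populations or {}
    vcf = VCF(str(path))
    ids = list(vcf.samples)
    samples = pd.DataFrame(
        {
            "id": ids,
            "population": [populations.get(s, s) for s in ids],
            "ploidy": [1 if s in pseudo_haploid else 2 for s in ids],
        }
    )
    ploidy = samples["ploidy"].to_numpy()

    records, rows, ancestral = [], [], {}
    n_dropped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_dropped += 1
            continue
        if v.REF not in _NUCLEOTIDES or v.ALT[0] not in _NUCLEOTIDES:
            n_dropped += 1
            continue
        # gt_types: 0=hom-ref 1=het 2=hom-alt(cyvcf2 uses 3) 2/3 per version
        g = v.genotype.array()
        alt_dose = (g[:, :2] == 1).sum(axis=1).astype(np.int8)
        miss = (g[:, :2] < 0).any(axis=1)
        alt_dose[miss] = MISSING
        haploid = ploidy == 1
        if haploid.any():
            alt_dose[haploid & (alt_dose == 2)] = 1
        records.append((str(v.CHROM), int(v.POS), v.REF, v.ALT[0]))
        rows.append(alt_dose)
        aa = v.INFO.get("AA")
        if aa:
            aa = str(aa).upper()
            if aa in _NUCLEOTIDES:
                ancestral[(str(v.CHROM), int(v.POS))] = aa
    if n_dropped:
        warnings.warn(f"{path}: dropped {n_dropped} multiallelic/indel records")
    sites = pd.DataFrame(records, columns=["chrom", "pos", "ref", "alt"])
    calls = np.array(rows, dtype=np.int8) if rows else np.empty((0, len(ids)), dtype=np.int8)
    out = PolarizedGenotypes(sites=sites, samples=samples, calls=calls)
    out.provenance.append(
        {"step": "read_vcf", "records_dropped": n_dropped, "aa_tags": len(ancestral)}
    )
    # stash AA tags so callers can polarize without re-reading the file
    out.ancestral_from_info = ancestral
    return out


def read_ancestral_table(path: str | Path) -> dict:
    """Two-column tab-separated table ``chrom:pos<TAB>allele`` → ancestral map."""
    out = {}
    for i, line in enumerate(Path(path).read_text().splitlines()):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"{path}, line {i + 1}: expected 2 tab-separated fields")
        key, allele = parts
        if ":" not in key:
            raise ParseError(f"{path}, line {i + 1}: site key must be chrom:pos")
        chrom, pos = key.rsplit(":", 1)
        try:
            pos = int(pos)
        except ValueError:
            raise ParseError(f"{path}, line {i + 1}: non-integer position {pos!r}")
        out[(chrom, pos)] = allele.strip().upper()
    return out
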