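"""Readers and writers for the package's plain-text formats.

* pedigree: whitespace-delimited linkage/PED-style columns
  (family_id, individual_id, father_id, mother_id, sex); "0" = absent parent
  or unknown sex; extra trailing columns are ignored with a warning.
* genotypes: transposed dosage TSV — one row per SNP, header
  ``snp_id`` then one ``family:individual`` column per person; entries
  0/1/2/NA.
* phenotypes: TSV with header family_id, individual_id, trait; NA missing
  ("-9" accepted with a warning).
* association/staged results: TSV with commented metadata header.

All writers emit ``#`` comment lines carrying the tool version and a config
hash; all readers skip them.
"""

from __future__ import annotations

import hashlib
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assoc import AssocResult
from .genotypes import MISSING, GenotypeMatrix
from .pedigree import Individual, KinshipMatrix, Pedigree, validate_pedigree

__all__ = [
    "read_pedigree",
    "write_pedigree",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "write_results",
    "read_results",
    "write_kinship",
    "read_config",
    "write_config",
    "ParseError",
]


class ParseError(ValueError):
    """A file-format error, carrying the offending line number."""


def _fmt_p(p) -> str:
    if p is None or (isinstance(p, float) and not np.isfinite(p)):
        return "NA"
    return f"{p:.4G}"


def _header_lines(config: dict | None = None) -> list[str]:
    lines = [f"# famstage {__version__}"]
    if config:
        blob = ";".join(f"{k}={config[k]}" for k in sorted(config))
        digest = hashlib.sha256(blob.encode()).hexdigest()[:12]
        lines.append(f"# config_hash {digest}")
        for k in sorted(config):
            lines.append(f"# config {k}={config[k]}")
    return lines


def read_pedigree(path: str | Path) -> Pedigree:
    """Parse a PED-style pedigree file and validate its structure."""
    inds: list[Individual] = []
    warned_extra = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 5:
                raise ParseError(
                    f"{path}:{lineno}: expected >= 5 columns "
                    f"(family, individual, father, mother, sex), got {len(parts)}"
                )
            if len(parts) > 5 and not warned_extra:
                warnings.warn(
                    f"{path}:{lineno}: ignoring extra columns beyond the "
                    "first five", stacklevel=2,
                )
                warned_extra = True
            fam, iid, fa, mo, sex = parts[:5]
            if sex not in ("0", "1", "2"):
                raise ParseError(
                    f"{path}:{lineno}: sex must be 0/1/2, got {sex!r}"
                )
            inds.append(
                Individual(
                    fam, iid,
                    father_id=None if fa == "0" else fa,
                    mother_id=None if mo == "0" else mo,
                    sex=int(sex),
                )
            )
    ped = Pedigree(inds)
    errs = validate_pedigree(ped)
    if errs:
        raise ParseError(f"{path}: invalid pedigree: " + "; ".join(errs))
    return ped


def write_pedigree(ped: Pedigree, path: str | Path,
                   config: dict | None = None) -> None:
    with open(path, "w") as fh:
        for line in _header_lines(config):
            fh.write(line + "\n")
        for ind in ped.individuals:
            fh.write(
                f"{ind.family_id}\t{ind.individual_id}\t"
                f"{ind.father_id or '0'}\t{ind.mother_id or '0'}\t{ind.sex}\n"
            )


def _key_token(key: tuple[str, str]) -> str:
    return f"{key[0]}:{key[1]}"


def write_genotypes(gm: GenotypeMatrix, path: str | Path,
                    config: dict | None = None) -> None:
    with open(path, "w") as fh:
        for line in _header_lines(config):
            fh.write(line + "\n")
        fh.write("snp_id\t" + "\t".join(_key_token(k) for k in gm.ids) + "\n")
        for j, snp in enumerate(gm.snp_ids):
            row = [
                "NA" if c == MISSING else str(int(c)) for c in gm.counts[:, j]
            ]
            fh.write(snp + "\t" + "\t".join(row) + "\n")


def read_genotypes(path: str | Path, ped: Pedigree) -> GenotypeMatrix:
    """Read a dosage TSV and align columns to the pedigree's order."""
    with open(path) as fh:
        lines = [
            (no, l.rstrip("\n")) for no, l in enumerate(fh, 1)
            if l.strip() and not l.startswith("#")
        ]
    if not lines:
        raise ParseError(f"{path}: empty genotype file")
    hdr_no, hdr = lines[0]
    cols = hdr.split("\t")
    if cols[0] != "snp_id":
        raise ParseError(f"{path}:{hdr_no}: first header column must be 'snp_id'")
    keys = []
    for tok in cols[1:]:
        fam, _, iid = tok.partition(":")
        if (fam, iid) not in ped.index:
            raise ParseError(f"{path}:{hdr_no}: unknown individual '{tok}'")
        keys.append((fam, iid))
    order = np.array([ped.index[k] for k in keys])
    if len(set(order)) != len(order):
        raise ParseError(f"{path}:{hdr_no}: duplicate individual column")
    snp_ids, rows = [], []
    for no, line in lines[1:]:
        parts = line.split("\t")
        if len(parts) != len(cols):
            raise ParseError(
                f"{path}:{no}: expected {len(cols)} columns, got {len(parts)}"
            )
        snp_ids.append(parts[0])
        vals = np.full(len(ped), MISSING, dtype=np.int8)
        for tok, idx in zip(parts[1:], order):
            if tok == "NA":
                continue
            if tok not in ("0", "1", "2"):
                raise ParseError(
                    f"{path}:{no}: SNP {parts[0]}, individual "
                    f"{_key_token(ped.ids[idx])}: dosage must be 0/1/2/NA, "
                    f"got {tok!r}"
                )
            vals[idx] = int(tok)
        rows.append(vals)
    return GenotypeMatrix(np.array(rows).T, snp_ids, ped.ids)


def write_phenotypes(ped: Pedigree, values: np.ndarray, path: str | Path,
                     config: dict | None = None) -> None:
    with open(path, "w") as fh:
        for line in _header_lines(config):
            fh.write(line + "\n")
        fh.write("family_id\tindividual_id\ttrait\n")
        for ind, v in zip(ped.individuals, values):
            tok = "NA" if not np.isfinite(v) else f"{v:.10G}"
            fh.write(f"{ind.family_id}\t{ind.individual_id}\t{tok}\n")


def read_phenotypes(path: str | Path, ped: Pedigree) -> np.ndarray:
    """Read a phenotype TSV, returning trait values aligned to ``ped.ids``
    (NaN where missing or absent from the file)."""
    values = np.full(len(ped), np.nan)
    seen: set[tuple[str, str]] = set()
    warned = False
    with open(path) as fh:
        for no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("family_id"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(f"{path}:{no}: expected 3 columns, got {len(parts)}")
            fam, iid, tok = parts
            key = (fam, iid)
            if key not in ped.index:
                raise ParseError(f"{path}:{no}: unknown individual {fam}:{iid}")
            if key in seen:
                raise ParseError(f"{path}:{no}: duplicate phenotype for {fam}:{iid}")
            seen.add(key)
            if tok in ("NA", ""):
                continue
            if tok == "-9":
                if not warned:
                    warnings.warn(
                        f"{path}:{no}: treating -9 as missing phenotype",
                        stacklevel=2,
                    )
                    warned = True
                continue
            try:
                values[ped.index[key]] = float(tok)
            except ValueError as exc:
                raise ParseError(f"{path}:{no}: bad trait value {tok!r}") from exc
    return values


RESULT_COLUMNS = ["snp_id", "method", "n_used", "beta", "se", "statistic",
                  "pvalue", "converged"]


def write_results(results: list[AssocResult], path: str | Path,
                  config: dict | None = None) -> None:
    with open(path, "w") as fh:
        for line in _header_lines(config):
            fh.write(line + "\n")
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in results:
            fh.write(
                "\t".join([
                    r.snp_id, r.method, str(r.n_used),
                    _fmt_p(r.beta), _fmt_p(r.se), _fmt_p(r.statistic),
                    _fmt_p(r.pvalue), str(int(r.converged)),
                ]) + "\n"
            )


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])


def write_kinship(kin: KinshipMatrix, path: str | Path,
                  config: dict | None = None) -> None:
    """Long-format TSV (id1, id2, kinship) of nonzero entries, upper triangle
    including the diagonal."""
    with open(path, "w") as fh:
        for line in _header_lines(config):
            fh.write(line + "\n")
        fh.write("id1\tid2\tkinship\n")
        for ix, block in zip(kin.family_indices, kin.blocks):
            for a in range(len(ix)):
                for b in range(a, len(ix)):
                    v = block[a, b]
                    if v != 0.0:
                        fh.write(
                            f"{_key_token(kin.ids[ix[a]])}\t"
                            f"{_key_token(kin.ids[ix[b]])}\t{v:.10G}\n"
                        )


def read_config(path: str | Path) -> dict[str, str]:
    """Flat ``key = value`` (or ``key=value``) configuration file."""
    cfg: dict[str, str] = {}
    with open(path) as fh:
        for no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ParseError(f"{path}:{no}: expected 'key = value'")
            k, _, v = line.partition("=")
            cfg[k.strip()] = v.strip()
    return cfg


def write_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        for line in _header_lines():
            fh.write(line + "\n")
        for k in sorted(cfg):
            fh.write(f"{k} = {cfg[k]}\n")
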