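"""LINKAGE pre-makeped pedigree files for simulated sibship datasets.

Each individual is one whitespace-delimited row:

    famID indID fatherID motherID sex affection allele1 allele2

with affection coded 2 = affected, 1 = unaffected, 0 = unknown (parents are
always phenotype-unknown) and marker alleles coded 1 for the variant of
interest and 2 for the non-carrier allele. The carrier parent (father,
indID 1) is ``1 2`` and the other parent (mother, indID 2) ``2 2``.

Proband designation is not part of the classical format, so it lives in a
companion YAML sidecar (``<file>.meta.yaml``) together with the generating
provenance; the pedigree file itself stays consumable by classical linkage
tools.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import yaml

from .models import Dataset

__all__ = ["write_ped", "read_ped", "sidecar_path"]

_CARRIER_ALLELES = ("1", "2")
_NONCARRIER_ALLELES = ("2", "2")


def sidecar_path(path) -> Path:
    return Path(str(path) + ".meta.yaml")


def write_ped(dataset: Dataset, path) -> Path:
    """Write a dataset as a pre-makeped pedigree file plus a YAML sidecar."""
    path = Path(path)
    lines = []
    for fam_idx in range(dataset.N):
        fam = fam_idx + 1
        lines.append(f"{fam} 1 0 0 1 0 {_CARRIER_ALLELES[0]} {_CARRIER_ALLELES[1]}")
        lines.append(f"{fam} 2 0 0 2 0 2 2")
        for sib_idx in range(dataset.s):
            ind = sib_idx + 3
            sex = 1 if sib_idx % 2 == 0 else 2
            aff = 2 if dataset.affected[fam_idx, sib_idx] else 1
            alleles = "1 2" if dataset.carrier[fam_idx, sib_idx] else "2 2"
            lines.append(f"{fam} {ind} 1 2 {sex} {aff} {alleles}")
    try:
        path.write_text("\n".join(lines) + "\n")
        meta = {
            "provenance": _plain(dataset.provenance),
            "probands": {
                str(i + 1): int(dataset.proband_index[i]) + 3
                for i in range(dataset.N)
                if dataset.proband_index[i] >= 0
            },
        }
        sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=False))
    except OSError as exc:
        raise OSError(f"failed writing pedigree file {path}: {exc}") from exc
    return path


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


class PedFormatError(ValueError):
    """Malformed pedigree file content, reported with a line number."""


def read_ped(path) -> Dataset:
    """Read a pre-makeped pedigree file written by :func:`write_ped`.

    Reconstructs the sibship dataset, picking proband designations up from
    the YAML sidecar when present. The expected mating type is one
    heterozygous carrier parent by one non-carrier parent; files that
    deviate (e.g. external data with two carrier parents) are accepted with
    a warning, since the likelihood modules can still be pointed at them
    after manual curation. Variable sibship sizes are not supported.
    """
    path = Path(path)
    families: dict[str, dict[str, tuple]] = {}
    try:
        text = path.read_text()
    except OSError as exc:
        raise OSError(f"failed reading pedigree file {path}: {exc}") from exc
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 8:
            raise PedFormatError(f"{path}:{lineno}: expected 8 columns, got {len(fields)}")
        fam, ind, father, mother, sex, aff, a1, a2 = fields
        if aff not in {"0", "1", "2"}:
            raise PedFormatError(f"{path}:{lineno}: affection must be 0/1/2, got {aff!r}")
        if a1 not in {"1", "2"} or a2 not in {"1", "2"}:
            raise PedFormatError(f"{path}:{lineno}: unknown marker allele code in {(a1, a2)!r}")
        families.setdefault(fam, {})
        if ind in families[fam]:
            raise PedFormatError(f"{path}:{lineno}: duplicate individual {ind} in family {fam}")
        families[fam][ind] = (father, mother, aff, a1, a2, lineno)
    if not families:
        raise PedFormatError(f"{path}: no pedigree rows found")

    probands: dict[str, int] = {}
    side = sidecar_path(path)
    provenance: dict = {}
    if side.exists():
        meta = yaml.safe_load(side.read_text()) or {}
        provenance = meta.get("provenance", {}) or {}
        probands = {str(k): int(v) for k, v in (meta.get("probands", {}) or {}).items()}

    carrier_rows, affected_rows, proband_rows = [], [], []
    for fam in sorted(families, key=_fam_key):
        members = families[fam]
        founders = {i for i, rec in members.items() if rec[0] == "0" and rec[1] == "0"}
        sibs = {i: rec for i, rec in members.items() if i not in founders}
        if not sibs:
            raise PedFormatError(f"{path}: family {fam} has no sibs")
        parent_ids = set()
        for ind, rec in sibs.items():
            father, mother = rec[0], rec[1]
            if father not in members or mother not in members:
                raise PedFormatError(
                    f"{path}:{rec[5]}: sib {ind} in family {fam} references absent parent(s)"
                )
            parent_ids |= {father, mother}
        if len(parent_ids) != 2:
            raise PedFormatError(f"{path}: family {fam} is not a single nuclear sibship")
        parent_carrier = sorted(_is_carrier(members[pid]) for pid in parent_ids)
        if parent_carrier != [False, True]:
            warnings.warn(
                f"family {fam}: expected one carrier (1 2) and one non-carrier (2 2) "
                "parent; downstream likelihoods assume that mating type",
                stacklevel=2,
            )
        sib_ids = sorted(sibs, key=_fam_key)
        carrier_rows.append([_is_carrier(members[i]) for i in sib_ids])
        affected_rows.append([members[i][2] == "2" for i in sib_ids])
        if fam in probands:
            try:
                proband_rows.append(sib_ids.index(str(probands[fam])))
            except ValueError:
                raise PedFormatError(f"{path}: sidecar proband {probands[fam]} not a sib of family {fam}")
        else:
            proband_rows.append(-1)

    sizes = {len(row) for row in carrier_rows}
    if len(sizes) != 1:
        raise PedFormatError(
            f"{path}: variable sibship sizes {sorted(sizes)} are not supported in one dataset"
        )
    return Dataset(
        np.array(carrier_rows, dtype=bool),
        np.array(affected_rows, dtype=bool),
        np.array(proband_rows, dtype=np.int64),
        provenance,
    )


def _is_carrier(rec) -> bool:
    return "1" in {rec[3], rec[4]}


def _fam_key(value: str):
    return (0, int(value)) if value.isdigit() else (1, value)
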