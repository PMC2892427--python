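"""Pedigree structures, validation, kinship, and nuclear-family decomposition.

A pedigree is the family-structure graph from which both the kinship-based
covariance of the mixed model and the Mendelian transmission law of the
family-based association test derive.  Individuals are keyed by
``(family_id, individual_id)`` so per-family individual ids may repeat across
families, as in linkage/PED files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Individual",
    "Pedigree",
    "KinshipMatrix",
    "NuclearFamily",
    "PedigreeError",
    "validate_pedigree",
    "compute_kinship",
    "extract_nuclear_families",
]

MALE, FEMALE, UNKNOWN = 1, 2, 0


class PedigreeError(ValueError):
    """Raised when an operation requires a structurally valid pedigree."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``father_id``/``mother_id`` are ``None`` for absent parents ("0" in PED
    files); a founder has both parents absent.  ``sex`` uses the linkage
    convention: 1 = male, 2 = female, 0 = unknown.
    """

    family_id: str
    individual_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: int = UNKNOWN

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None

    @property
    def key(self) -> tuple[str, str]:
        return (self.family_id, self.individual_id)


@dataclass(frozen=True)
class NuclearFamily:
    """A (father, mother, offspring) unit usable by the FBAT engine.

    Indices refer to positions in the owning :class:`Pedigree`.  Both parents
    are genotyped by construction (see :func:`extract_nuclear_families`).
    """

    father: int
    mother: int
    offspring: tuple[int, ...]


class Pedigree:
    """An ordered collection of individuals partitioned into families.

    Provides index maps, founder/non-founder partition and the generation
    levels used for vectorised gene dropping (parents always appear in an
    earlier level than their children).
    """

    def __init__(self, individuals: list[Individual]):
        self.individuals: list[Individual] = list(individuals)
        self.index: dict[tuple[str, str], int] = {}
        for i, ind in enumerate(self.individuals):
            if ind.key in self.index:
                raise PedigreeError(f"duplicate individual id {ind.key}")
            self.index[ind.key] = i
        self.families: dict[str, list[int]] = {}
        for i, ind in enumerate(self.individuals):
            self.families.setdefault(ind.family_id, []).append(i)

    def __len__(self) -> int:
        return len(self.individuals)

    @property
    def ids(self) -> list[tuple[str, str]]:
        return [ind.key for ind in self.individuals]

    def parent_indices(self, i: int) -> tuple[int | None, int | None]:
        ind = self.individuals[i]
        fa = self.index.get((ind.family_id, ind.father_id)) if ind.father_id else None
        mo = self.index.get((ind.family_id, ind.mother_id)) if ind.mother_id else None
        return fa, mo

    @cached_property
    def founder_mask(self) -> np.ndarray:
        return np.array([ind.is_founder for ind in self.individuals], dtype=bool)

    @cached_property
    def depths(self) -> np.ndarray:
        """Generation depth: 0 for founders, 1 + max(parent depths) otherwise.

        Raises :class:`PedigreeError` on a parental cycle.
        """
        n = len(self)
        depth = np.full(n, -1, dtype=int)
        state = np.zeros(n, dtype=np.int8)  # 0 unvisited, 1 in progress, 2 done

        def visit(i: int) -> int:
            if state[i] == 2:
                return depth[i]
            if state[i] == 1:
                raise PedigreeError(
                    f"cycle in pedigree at individual {self.individuals[i].key}"
                )
            state[i] = 1
            fa, mo = self.parent_indices(i)
            d = 0
            for p in (fa, mo):
                if p is not None:
                    d = max(d, visit(p) + 1)
            depth[i] = d
            state[i] = 2
            return d

        # iterative wrapper to avoid recursion limits on deep pedigrees
        import sys

        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 2 * n + 100))
        try:
            for i in range(n):
                visit(i)
        finally:
            sys.setrecursionlimit(old)
        return depth

    @cached_property
    def transmission_levels(self) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Per generation, arrays (child, father, mother) of pedigree indices.

        Only non-founders with BOTH parents present appear; half-founders
        (one parent listed) are rejected by validation before simulation.
        """
        levels: dict[int, list[tuple[int, int, int]]] = {}
        for i in range(len(self)):
            fa, mo = self.parent_indices(i)
            if fa is not None and mo is not None:
                levels.setdefault(int(self.depths[i]), []).append((i, fa, mo))
        out = []
        for d in sorted(levels):
            arr = np.asarray(levels[d], dtype=np.intp)
            out.append((arr[:, 0], arr[:, 1], arr[:, 2]))
        return out


def validate_pedigree(ped: Pedigree) -> list[str]:
    """Return structural errors; an empty list means the pedigree is valid.

    Checks: parent references resolve within the same family, parents come in
    pairs, sexes of referenced parents are consistent (father male or unknown,
    mother female or unknown), and the parent graph is acyclic.
    """
    errors: list[str] = []
    for ind in ped.individuals:
        for role, pid, want_sex in (
            ("father", ind.father_id, MALE),
            ("mother", ind.mother_id, FEMALE),
        ):
            if pid is None:
                continue
            j = ped.index.get((ind.family_id, pid))
            if j is None:
                # distinguish cross-family reference from a truly unknown id
                in_other = any(
                    other.individual_id == pid and other.family_id != ind.family_id
                    for other in ped.individuals
                )
                kind = "references another family" if in_other else "not found"
                errors.append(
                    f"{ind.key}: {role} '{pid}' {kind}"
                )
                continue
            parent = ped.individuals[j]
            if parent.sex not in (want_sex, UNKNOWN):
                errors.append(
                    f"{ind.key}: {role} '{pid}' has inconsistent sex {parent.sex}"
                )
        if (ind.father_id is None) != (ind.mother_id is None):
            errors.append(f"{ind.key}: exactly one parent listed (need zero or two)")
    try:
        ped.depths
    except PedigreeError as exc:
        errors.append(str(exc))
    return errors


class KinshipMatrix:
    """Block-diagonal kinship coefficients phi, one block per family.

    ``2 * phi`` is the additive-relationship correlation used by the mixed
    model.  Blocks are stored dense per family; cross-family entries are
    structurally zero.  Eigen- and Cholesky-decompositions of the full
    2*phi matrix are cached for fast repeated mixed-model fits and trait
    simulation.
    """

    def __init__(self, ids: list[tuple[str, str]], family_indices: list[np.ndarray],
                 blocks: list[np.ndarray]):
        self.ids = list(ids)
        self.family_indices = [np.asarray(ix, dtype=np.intp) for ix in family_indices]
        self.blocks = [np.asarray(b, dtype=float) for b in blocks]
        self._index = {key: i for i, key in enumerate(self.ids)}
        self.n = len(self.ids)

    def to_dense(self) -> np.ndarray:
        phi = np.zeros((self.n, self.n))
        for ix, b in zip(self.family_indices, self.blocks):
            phi[np.ix_(ix, ix)] = b
        return phi

    @cached_property
    def eigen2phi(self) -> tuple[sp.csr_matrix, np.ndarray]:
        """(U, d) with 2*phi = U diag(d) U', U block-orthogonal and sparse."""
        rows, cols, vals = [], [], []
        d = np.empty(self.n)
        for ix, b in zip(self.family_indices, self.blocks):
            w, v = np.linalg.eigh(2.0 * b)
            w = np.clip(w, 0.0, None)
            d[ix] = w
            r = np.repeat(ix, len(ix))
            c = np.tile(ix, len(ix))
            rows.append(r)
            cols.append(c)
            vals.append(v.ravel())
        U = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n, self.n),
        )
        return U, d

    @cached_property
    def chol2phi(self) -> sp.csr_matrix:
        """Sparse lower factor L with L @ L.T = 2*phi (eigen square root)."""
        U, d = self.eigen2phi
        return (U @ sp.diags(np.sqrt(d))).tocsr()

    def subset(self, indices: np.ndarray) -> "KinshipMatrix":
        """Kinship restricted to ``indices`` (pedigree positions), kept in order."""
        indices = np.asarray(indices, dtype=np.intp)
        pos = {int(g): k for k, g in enumerate(indices)}
        new_ids = [self.ids[int(g)] for g in indices]
        fam_ix, blocks = [], []
        for ix, b in zip(self.family_indices, self.blocks):
            keep = [k for k, g in enumerate(ix) if int(g) in pos]
            if not keep:
                continue
            fam_ix.append(np.array([pos[int(ix[k])] for k in keep], dtype=np.intp))
            blocks.append(b[np.ix_(keep, keep)])
        return KinshipMatrix(new_ids, fam_ix, blocks)


def compute_kinship(ped: Pedigree) -> KinshipMatrix:
    """Kinship coefficients by the tabular recursion, per family block.

    For individuals ordered so parents precede children::

        phi(i, i) = (1 + phi(f_i, m_i)) / 2        (1/2 for founders)
        phi(i, j) = (phi(f_i, j) + phi(m_i, j)) / 2,  j earlier than i

    Founders are mutually unrelated.  The recursion handles inbred loops
    without special casing.
    """
    errs = validate_pedigree(ped)
    if errs:
        raise PedigreeError("invalid pedigree: " + "; ".join(errs))
    depths = ped.depths
    fam_indices, blocks = [], []
    for fam in ped.families.values():
        ix = np.asarray(fam, dtype=np.intp)
        order = ix[np.argsort(depths[ix], kind="stable")]
        local = {int(g): k for k, g in enumerate(order)}
        m = len(order)
        phi = np.zeros((m, m))
        for k, g in enumerate(order):
            fa, mo = ped.parent_indices(int(g))
            if fa is None:
                phi[k, k] = 0.5
            else:
                lf, lm = local[fa], local[mo]
                phi[k, k] = 0.5 * (1.0 + phi[lf, lm])
                for j in range(k):
                    phi[k, j] = phi[j, k] = 0.5 * (phi[lf, j] + phi[lm, j])
        fam_indices.append(order)
        blocks.append(phi)
    return KinshipMatrix(ped.ids, fam_indices, blocks)


def extract_nuclear_families(
    ped: Pedigree, genotyped: set[tuple[str, str]] | None = None
) -> list[NuclearFamily]:
    """Decompose a pedigree into FBAT-usable nuclear units.

    A unit is every (father, mother) mating pair with at least one genotyped
    offspring where BOTH parents are genotyped; an individual may be offspring
    in one unit and a parent in another.  ``genotyped`` holds
    ``(family_id, individual_id)`` keys; ``None`` means everyone is genotyped.
    """
    if genotyped is None:
        genotyped = set(ped.ids)
    units: dict[tuple[int, int], list[int]] = {}
    for i in range(len(ped)):
        fa, mo = ped.parent_indices(i)
        if fa is None or mo is None:
            continue
        units.setdefault((fa, mo), []).append(i)
    out = []
    for (fa, mo), kids in sorted(units.items()):
        if ped.individuals[fa].key not in genotyped:
            continue
        if ped.individuals[mo].key not in genotyped:
            continue
        kids_g = tuple(k for k in kids if ped.individuals[k].key in genotyped)
        if kids_g:
            out.append(NuclearFamily(father=fa, mother=mo, offspring=kids_g))
    return out
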