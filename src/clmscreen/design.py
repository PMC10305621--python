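"""Construction and validation of pooled incubation designs, and assay economics.

A pooling design assigns each strain of a library to one or more incubation
batches; the batch membership pattern of a strain is its *signature*.  After
one pooled round, the set of active batches (the hit set) is decoded against
the signatures: with a single active strain and distinct signatures, the hit
set pinpoints the strain; unions of signatures handle multiple actives.

Designs here are tiny (tens of strains, a handful of batches), so
separability is checked by exhaustive enumeration rather than algebraic
(d-disjunct) constructions.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field
from math import comb

import numpy as np

__all__ = [
    "PoolDesign",
    "AssayPlan",
    "DesignCapacityError",
    "ValidationReport",
    "build_design",
    "validate_design",
    "assay_count",
    "default_batch_labels",
    "default_strain_labels",
]


class DesignCapacityError(ValueError):
    """The requested design is infeasible (slots, replication or distinctness)."""


def default_batch_labels(n: int) -> list[str]:
    """Consecutive letters 'A', 'B', ... (double letters past 26)."""
    letters = string.ascii_uppercase
    labels = []
    for i in range(n):
        if i < 26:
            labels.append(letters[i])
        else:
            labels.append(letters[i // 26 - 1] + letters[i % 26])
    return labels

def default_strain_labels(n: int) -> list[str]:
    return [f"s{i + 1:02d}" for i in range(n)]


@dataclass(frozen=True)
class PoolDesign:
    """Binary strain x batch incidence matrix with pooling metadata.

    Every batch (column) contains exactly ``pool_size`` strains, and every
    strain appears in at least one batch.
    """

    n_strains: int
    n_batches: int
    incidence: np.ndarray
    pool_size: int
    strain_ids: tuple[str, ...]
    batch_ids: tuple[str, ...]
    seed: int | None = None

    def __post_init__(self) -> None:
        M = np.asarray(self.incidence)
        if M.shape != (self.n_strains, self.n_batches):
            raise ValueError(
                f"incidence shape {M.shape} != ({self.n_strains}, {self.n_batches})"
            )
        if not np.isin(M, (0, 1)).all():
            raise ValueError("incidence entries must be 0/1")
        col = M.sum(axis=0)
        if not (col == self.pool_size).all():
            raise ValueError(f"batch sizes {col.tolist()} != pool_size {self.pool_size}")
        if (M.sum(axis=1) < 1).any():
            raise ValueError("every strain must appear in at least one batch")
        if len(self.strain_ids) != self.n_strains or len(self.batch_ids) != self.n_batches:
            raise ValueError("label lengths do not match matrix dimensions")

    def signature(self, strain_id: str) -> frozenset[str]:
        """Set of batch ids containing the strain."""
        i = self.strain_ids.index(strain_id)
        return frozenset(
            b for b, x in zip(self.batch_ids, self.incidence[i]) if x
        )

    def signatures(self) -> dict[str, frozenset[str]]:
        return {s: self.signature(s) for s in self.strain_ids}

    def members(self, batch_id: str) -> list[str]:
        """Strain ids pooled in the given batch."""
        j = self.batch_ids.index(batch_id)
        return [s for s, x in zip(self.strain_ids, self.incidence[:, j]) if x]


@dataclass(frozen=True)
class AssayPlan:
    """Assay-count accounting of a pooled screen versus conventional screening."""

    pooled_assays: int
    confirmatory_assays: int
    conventional: int

    @property
    def total(self) -> int:
        return self.pooled_assays + self.confirmatory_assays

    @property
    def savings(self) -> int:
        return self.conventional - self.total

    def to_dict(self) -> dict[str, int]:
        return {
            "pooled_assays": self.pooled_assays,
            "confirmatory_assays": self.confirmatory_assays,
            "total": self.total,
            "conventional": self.conventional,
            "savings": self.savings,
        }


def _replication_quotas(n_strains: int, n_batches: int, pool_size: int) -> np.ndarray:
    """Per-strain replication: floor/ceil split of slots over strains.

    With ``slots = n_batches * pool_size``, the ``slots mod n_strains``
    surplus strains get the ceiling replication; e.g. 12 strains in 4 batches
    of 5 gives 20 slots: 8 strains in two batches and 4 in one.
    """
    slots = n_batches * pool_size
    base, extra = divmod(slots, n_strains)
    return np.array([base + 1] * extra + [base] * (n_strains - extra))


def build_design(
    n_strains: int,
    n_batches: int,
    pool_size: int,
    seed: int | None = None,
    distinct_signatures: bool = False,
    strain_ids: list[str] | None = None,
    batch_ids: list[str] | None = None,
    max_attempts: int = 200,
) -> PoolDesign:
    """Randomly assemble a pooled design under replication quotas.

    Strains are assigned (in seeded random order) to the batches with most
    free slots, which guarantees every batch fills to ``pool_size`` exactly
    when capacity suffices.  With ``distinct_signatures`` the construction is
    retried (bounded) until all strain signatures are pairwise distinct.

    Raises
    ------
    DesignCapacityError
        If ``n_batches * pool_size < n_strains``, if a quota exceeds
        ``n_batches``, or if distinct signatures are combinatorially
        impossible for the quota profile.
    """
    if n_strains < 1 or n_batches < 1 or pool_size < 1:
        raise ValueError("n_strains, n_batches and pool_size must be >= 1")
    if pool_size > n_strains:
        raise DesignCapacityError(
            f"pool_size {pool_size} exceeds n_strains {n_strains}"
        )
    slots = n_batches * pool_size
    if slots < n_strains:
        raise DesignCapacityError(
            f"{slots} slots ({n_batches} batches x pool size {pool_size}) "
            f"cannot hold {n_strains} strains"
        )
    quotas = _replication_quotas(n_strains, n_batches, pool_size)
    if quotas.max() > n_batches:
        raise DesignCapacityError(
            f"replication {quotas.max()} exceeds n_batches {n_batches}"
        )
    if distinct_signatures:
        # signatures available per replication level
        for r in np.unique(quotas):
            if np.sum(quotas == r) > comb(n_batches, int(r)):
                raise DesignCapacityError(
                    f"{np.sum(quotas == r)} strains need distinct signatures of "
                    f"size {r} but only {comb(n_batches, int(r))} exist"
                )

    s_ids = tuple(strain_ids or default_strain_labels(n_strains))
    b_ids = tuple(batch_ids or default_batch_labels(n_batches))
    rng = np.random.default_rng(seed)

    for _ in range(max_attempts):
        M = np.zeros((n_strains, n_batches), dtype=int)
        capacity = np.full(n_batches, pool_size)
        order = rng.permutation(n_strains)
        shuffled_quotas = rng.permutation(quotas)
        ok = True
        for i in order:
            r = int(shuffled_quotas[i])
            # batches with most free slots, random tie-break
            noise = rng.random(n_batches)
            pick = np.lexsort((noise, -capacity))[:r]
            if capacity[pick].min() < 1:
                ok = False
                break
            M[i, pick] = 1
            capacity[pick] -= 1
        if not ok:
            continue
        if distinct_signatures:
            sigs = {tuple(row) for row in M}
            if len(sigs) < n_strains:
                continue
        return PoolDesign(
            n_strains=n_strains,
            n_batches=n_batches,
            incidence=M,
            pool_size=pool_size,
            strain_ids=s_ids,
            batch_ids=b_ids,
            seed=seed,
        )
    raise DesignCapacityError(
        f"could not satisfy constraints in {max_attempts} attempts"
    )


@dataclass(frozen=True)
class ValidationReport:
    all_signatures_distinct: bool
    separable: bool
    max_actives: int
    collision_groups: tuple[tuple[str, ...], ...]
    colliding_unions: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]


def validate_design(d: PoolDesign, max_actives: int = 1) -> ValidationReport:
    """Check signature distinctness and ``max_actives``-separability.

    A design is d-separable when the unions of up to d strain signatures are
    pairwise distinct, so any set of at most d active strains is decodable
    from the hit set alone.  Checked by exhaustive enumeration of subsets
    (designs here are small).  Strains sharing an identical signature are
    reported as collision groups — such strains are indistinguishable by the
    pooled round and all become candidates together.
    """
    sigs = d.signatures()
    by_sig: dict[frozenset[str], list[str]] = {}
    for s, sig in sigs.items():
        by_sig.setdefault(sig, []).append(s)
    collisions = tuple(
        tuple(sorted(group)) for group in by_sig.values() if len(group) > 1
    )

    union_of: dict[frozenset[str], tuple[str, ...]] = {}
    colliding_unions: list[tuple[tuple[str, ...], tuple[str, ...]]] = []
    for r in range(1, max_actives + 1):
        for subset in itertools.combinations(sorted(d.strain_ids), r):
            u = frozenset().union(*(sigs[s] for s in subset))
            if u in union_of and set(union_of[u]) != set(subset):
                colliding_unions.append((union_of[u], subset))
            else:
                union_of.setdefault(u, subset)
    return ValidationReport(
        all_signatures_distinct=not collisions,
        separable=not colliding_unions,
        max_actives=max_actives,
        collision_groups=collisions,
        colliding_unions=tuple(colliding_unions),
    )


def assay_count(
    d: PoolDesign,
    n_substrate_mixtures: int = 1,
    n_substrates: int = 1,
    n_confirmations: int = 0,
) -> AssayPlan:
    """Assay economics: pooled round + confirmations vs one-strain-one-substrate.

    ``pooled = n_batches * n_substrate_mixtures`` incubations; conventional
    screening needs ``n_strains * n_substrates``.  Confirmatory (individual)
    assays are an input — how many are needed depends on how the hit patterns
    decode, which this function does not see.
    """
    if min(n_substrate_mixtures, n_substrates, n_confirmations) < 0:
        raise ValueError("counts must be >= 0")
    return AssayPlan(
        pooled_assays=d.n_batches * n_substrate_mixtures,
        confirmatory_assays=n_confirmations,
        conventional=d.n_strains * n_substrates,
    )
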