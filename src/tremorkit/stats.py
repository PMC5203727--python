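"""Permutational MANOVA (PERMANOVA) on 2-D projections.

Distance-based nonparametric one-way MANOVA (Anderson 2001). With
Euclidean distances d_ij over N observations in a groups,

    SS_total = (1/N) sum_{i<j} d_ij^2
    SS_within = sum_g (1/n_g) sum_{i<j in g} d_ij^2
    SS_among = SS_total - SS_within
    pseudo-F = (SS_among / (a - 1)) / (SS_within / (N - a))

and the p-value refers pseudo-F to its permutation null, obtained by
randomly relabelling observations. The convention

    p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations)

guarantees p > 0; ties count as exceedances (conservative). Pairwise
group comparisons multiply raw p-values by the number of pairs
(Bonferroni), capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.spatial.distance import pdist, squareform


@dataclass
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    group_sizes: dict[str, int]
    pairwise: list[tuple[tuple[str, str], float, float]] = field(
        default_factory=list
    )  # (pair, raw p, Bonferroni p)


def _pseudo_f_stats(d2: np.ndarray, labels: np.ndarray,
                    groups: np.ndarray) -> float:
    """pseudo-F from a squared-distance matrix and a label vector."""
    N = d2.shape[0]
    a = len(groups)
    ss_total = d2[np.triu_indices(N, k=1)].sum() / N
    ss_within = 0.0
    for g in groups:
        mask = labels == g
        n_g = int(mask.sum())
        sub = d2[np.ix_(mask, mask)]
        ss_within += sub[np.triu_indices(n_g, k=1)].sum() / n_g
    ss_among = ss_total - ss_within
    if ss_within <= 0:
        return np.inf
    return (ss_among / (a - 1)) / (ss_within / (N - a))


def permanova(
    coords: np.ndarray,
    labels,
    n_permutations: int = 10_000,
    seed: int | None = 0,
    subject_ids=None,
) -> PermanovaResult:
    """One-way PERMANOVA with Euclidean distances and label permutation.

    Requires at least two groups of at least two observations each and
    a non-degenerate coordinate cloud.

    By default labels are permuted at the observation level. When
    repeated observations per subject are present (several task windows
    of one subject) they are not exchangeable under a subject-level
    null; passing ``subject_ids`` permutes group labels across whole
    subjects instead, each subject's observations moving together.
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray([str(l) for l in labels])
    if coords.ndim != 2 or coords.shape[0] != labels.shape[0]:
        raise ValueError("coords and labels must align")
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if counts.min() < 2:
        raise ValueError("every group needs at least 2 observations")
    d2 = squareform(pdist(coords)) ** 2
    if not d2[np.triu_indices(len(labels), k=1)].any():
        raise ValueError("degenerate input: all observations identical")

    f_obs = _pseudo_f_stats(d2, labels, groups)
    rng = np.random.default_rng(seed)
    # indicator-matrix formulation: SS_within per permutation from
    # diag(M' D2 M) with M the one-hot label matrix
    N = len(labels)
    label_idx = np.searchsorted(groups, labels)
    if subject_ids is not None:
        subject_ids = np.asarray([str(s) for s in subject_ids])
        if subject_ids.shape[0] != N:
            raise ValueError("subject_ids must align with labels")
        uniq_subj, subj_inv = np.unique(subject_ids, return_inverse=True)
        subj_label = np.empty(len(uniq_subj), dtype=int)
        subj_label[subj_inv] = label_idx  # one group per subject
    n_exceed = 0
    inv_counts = 1.0 / counts
    ss_total = d2[np.triu_indices(N, k=1)].sum() / N
    a = len(groups)
    for _ in range(n_permutations):
        if subject_ids is None:
            perm = rng.permutation(label_idx)
        else:
            perm = rng.permutation(subj_label)[subj_inv]
        M = np.zeros((N, a))
        M[np.arange(N), perm] = 1.0
        quad = np.einsum("ia,ij,ja->a", M, d2, M) / 2.0
        if subject_ids is None:
            ss_within = float((quad * inv_counts).sum())
        else:
            # subject-level shuffles may change per-group observation
            # counts when subjects contribute unequal window numbers
            counts_perm = M.sum(axis=0)
            if counts_perm.min() < 1:
                continue
            ss_within = float((quad / counts_perm).sum())
        ss_among = ss_total - ss_within
        if ss_within <= 0:
            f_perm = np.inf
        else:
            f_perm = (ss_among / (a - 1)) / (ss_within / (N - a))
        if f_perm >= f_obs:
            n_exceed += 1
    p = (1 + n_exceed) / (1 + n_permutations)
    return PermanovaResult(
        pseudo_F=float(f_obs),
        p_value=float(p),
        n_permutations=n_permutations,
        group_sizes={g: int(c) for g, c in zip(groups, counts)},
    )


def pairwise_bonferroni(
    coords: np.ndarray,
    labels,
    n_permutations: int = 10_000,
    seed: int | None = 0,
    subject_ids=None,
) -> list[tuple[tuple[str, str], float, float]]:
    """PERMANOVA on every group pair with Bonferroni-corrected p-values."""
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray([str(l) for l in labels])
    if subject_ids is not None:
        subject_ids = np.asarray([str(s) for s in subject_ids])
    groups = np.unique(labels)
    pairs = list(combinations(groups, 2))
    n_pairs = len(pairs)
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    child_seeds = ss.generate_state(n_pairs) % (2**31)
    out = []
    for (ga, gb), child in zip(pairs, child_seeds):
        mask = (labels == ga) | (labels == gb)
        res = permanova(
            coords[mask],
            labels[mask],
            n_permutations,
            int(child),
            subject_ids=subject_ids[mask] if subject_ids is not None else None,
        )
        raw = res.p_value
        out.append(((str(ga), str(gb)), raw, min(1.0, raw * n_pairs)))
    return out


def permanova_with_pairwise(
    coords,
    labels,
    n_permutations: int = 10_000,
    seed: int | None = 0,
    subject_ids=None,
) -> PermanovaResult:
    """Omnibus test plus Bonferroni-corrected pairwise comparisons."""
    res = permanova(coords, labels, n_permutations, seed, subject_ids)
    res.pairwise = pairwise_bonferroni(
        coords, labels, n_permutations, seed, subject_ids
    )
    return res
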