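"""Synthetic compendium, genome, and draft-TRN generators with known ground truth.

Every downstream stage of the pipeline (QC filtering, ICA decomposition,
regulon enrichment, operon clustering, motif scanning, regulon-membership
classification) gets its parameter-recovery test from these generators: they
plant regulatory modules, replicate structure, operon layouts and promoter
motifs whose exact composition is returned alongside the data.

The expression model is the module decomposition X = M.A + noise, where M is
a sparse gene-weight matrix (disjoint gene blocks, one per planted module)
and A holds condition-level activities shared across biological replicates.
Replicate-level activity jitter is solved in closed form so that the expected
within-condition Pearson correlation across genes matches ``replicate_rho``.
Noise is Gaussian on the logTPM scale; count-level noise is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import rng_from
from .qc import ExpressionCompendium

BASES = "ACGT"

__all__ = [
    "GroundTruth",
    "GenomeTruth",
    "generate_compendium",
    "generate_genome",
    "generate_trn_table",
]


@dataclass
class GroundTruth:
    """Planted structure behind a synthetic compendium.

    ``module_weights`` (genes x K) and ``module_activities`` (K x samples)
    are the planted M and A matrices; ``regulon_labels`` maps a regulator
    name ("R1", "R2", ...) to the gene set of its planted module.
    """

    module_weights: pd.DataFrame
    module_activities: pd.DataFrame
    noise_sd: float
    replicate_rho: float
    regulon_labels: dict[str, set[str]]
    seed: int
    motif_pwm: np.ndarray | None = None
    planted_site_positions: dict[str, int] = field(default_factory=dict)

    @property
    def k_modules(self) -> int:
        return self.module_weights.shape[1]


@dataclass
class GenomeTruth:
    """Planted operon layout and motif positions for a synthetic genome."""

    genes: pd.DataFrame  # gene_id, accession, start, end, strand, operon_id
    promoters: dict[str, str]  # lead gene id -> upstream sequence
    operons: dict[str, list[str]]  # operon_id -> ordered gene ids
    planted_site_positions: dict[str, int]  # lead gene id -> 0-based offset
    motif_pwm: np.ndarray | None
    seed: int


def _module_weight_matrix(
    n_genes: int, k_modules: int, gene_ids: list[str], rng: np.random.Generator
) -> pd.DataFrame:
    """Sparse disjoint module weights: half the genes belong to a module.

    Weight magnitudes are Uniform(1, 2) with random sign, which keeps every
    member well above typical logTPM noise levels and makes the gene-weight
    distribution of each component strongly non-Gaussian (the property ICA
    exploits).
    """
    member_total = n_genes // 2
    block = max(2, member_total // k_modules)
    W = np.zeros((n_genes, k_modules))
    order = rng.permutation(n_genes)
    for k in range(k_modules):
        members = order[k * block : (k + 1) * block]
        w = rng.uniform(1.5, 2.5, size=members.size)
        w *= rng.choice([-1.0, 1.0], size=members.size)
        W[members, k] = w
    return pd.DataFrame(W, index=gene_ids, columns=[f"mod_{k}" for k in range(k_modules)])


def _solve_independent_variance(
    module_var: np.ndarray, rho: float, n_draws: int = 4000
) -> float:
    """Per-column independent variance c such that E[V / (V + c)] = rho.

    V is the realized per-condition signal variance across genes,
    V = sum_k q_k a_k^2 with a ~ N(0, I); the expectation is evaluated by
    Monte Carlo (fixed internal stream, so the generator stays
    deterministic) and c found by bisection. Solving the exact expectation
    rather than the first-order ratio keeps the achieved within-replicate
    correlation on target despite the heavy right skew of V.
    """
    mc = np.random.default_rng(123456789)
    a2 = mc.standard_normal((n_draws, module_var.size)) ** 2
    V = a2 @ module_var
    if rho >= 1.0:
        return 0.0

    def expected_r(c: float) -> float:
        return float(np.mean(V / (V + c)))

    lo, hi = 0.0, float(V.mean()) * 1e4 + 1.0
    for _ in range(200):
        mid = (lo + hi) / 2
        if expected_r(mid) > rho:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def generate_compendium(
    n_genes: int = 2000,
    n_conditions: int = 50,
    replicates_per_condition: int = 2,
    k_modules: int = 35,
    noise_sd: float = 0.25,
    replicate_rho: float = 0.9,
    seed: int = 0,
    n_projects: int = 13,
) -> tuple[ExpressionCompendium, GroundTruth]:
    """Generate a logTPM-scale expression compendium with planted modules.

    Defaults emulate a bacterial RNA-seq compendium of ~100 samples over 50
    conditions grouped into 13 projects (media types), with ~35 independently
    modulated gene sets. Conditions are chunked into near-equal projects and
    the first condition of each project is flagged as its reference.

    Returns the compendium (values + per-sample metadata) and the
    :class:`GroundTruth` that produced it.
    """
    n_samples = n_conditions * replicates_per_condition
    if not (0 < replicate_rho <= 1):
        raise ValueError(f"replicate_rho must be in (0, 1], got {replicate_rho}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if replicates_per_condition < 2:
        raise ValueError("replicates_per_condition must be >= 2")
    if k_modules >= min(n_genes, n_samples):
        raise ValueError(
            f"k_modules={k_modules} must be < min(n_genes, n_samples)={min(n_genes, n_samples)}"
        )
    n_projects = min(n_projects, n_conditions)

    rng = rng_from(seed, "compendium")
    gene_ids = [f"gene_{i:04d}" for i in range(n_genes)]
    M = _module_weight_matrix(n_genes, k_modules, gene_ids, rng)
    W = M.to_numpy()

    # Condition-level activities, shared by all replicates of a condition.
    A_cond = rng.standard_normal((k_modules, n_conditions))

    # Replicate jitter solved from replicate_rho. The per-column independent
    # variance c* satisfying E[V / (V + c*)] = rho is found numerically
    # (V = realized signal variance across genes); noise_sd^2 is already
    # spent on i.i.d. measurement noise and the remainder goes to activity
    # jitter, which reaches the genes through M (variance tau^2 * ||M||_F^2/G
    # per column). If measurement noise alone exceeds the budget, tau = 0 and
    # the achieved correlation falls below the target.
    module_var = (W**2).sum(axis=0) / n_genes  # q_k per module
    v_sig = float(module_var.sum())
    c_star = _solve_independent_variance(module_var, replicate_rho)
    tau2 = max(0.0, (c_star - noise_sd**2) / v_sig) if v_sig > 0 else 0.0
    tau = np.sqrt(tau2)

    sample_ids, conditions, replicates = [], [], []
    A_rep = np.zeros((k_modules, n_samples))
    for c in range(n_conditions):
        for r in range(replicates_per_condition):
            j = c * replicates_per_condition + r
            sample_ids.append(f"cond{c:02d}_r{r + 1}")
            conditions.append(f"cond{c:02d}")
            replicates.append(r + 1)
            A_rep[:, j] = A_cond[:, c] + tau * rng.standard_normal(k_modules)

    X = W @ A_rep
    if noise_sd > 0:
        X = X + noise_sd * rng.standard_normal(X.shape)

    # Chunk conditions into projects; first condition of each project is the
    # reference condition.
    bounds = np.linspace(0, n_conditions, n_projects + 1).astype(int)
    cond_project = {}
    cond_is_ref = {}
    for p in range(n_projects):
        chunk = range(bounds[p], bounds[p + 1])
        for i, c in enumerate(chunk):
            cond_project[f"cond{c:02d}"] = f"project_{p:02d}"
            cond_is_ref[f"cond{c:02d}"] = i == 0

    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "project": [cond_project[c] for c in conditions],
            "condition": conditions,
            "replicate_index": replicates,
            "is_reference": [cond_is_ref[c] for c in conditions],
            "mapped_reads": rng.integers(2_000_000, 20_000_000, size=n_samples),
            "fastqc_pass": True,
        }
    ).set_index("sample_id")

    compendium = ExpressionCompendium(
        data=pd.DataFrame(X, index=gene_ids, columns=sample_ids), metadata=meta
    )
    regulons = {
        f"R{k + 1}": set(M.index[M.iloc[:, k] != 0]) for k in range(k_modules)
    }
    truth = GroundTruth(
        module_weights=M,
        module_activities=pd.DataFrame(
            A_rep, index=M.columns, columns=sample_ids
        ),
        noise_sd=noise_sd,
        replicate_rho=replicate_rho,
        regulon_labels=regulons,
        seed=seed,
    )
    return compendium, truth


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def _sample_site(pwm: np.ndarray, rng: np.random.Generator, consensus: bool) -> str:
    if consensus:
        return "".join(BASES[j] for j in pwm.argmax(axis=1))
    return "".join(
        BASES[rng.choice(4, p=pwm[i] / pwm[i].sum())] for i in range(pwm.shape[0])
    )


def generate_genome(
    n_genes: int,
    n_operons: int,
    gap_within: int = 50,
    gap_between: int = 600,
    seed: int = 0,
    gene_length: int = 900,
    promoter_length: int = 300,
    motif_pwm: np.ndarray | None = None,
    motif_operons: float | list[str] = 0.0,
    plant_consensus: bool = False,
    n_accessions: int = 1,
) -> GenomeTruth:
    """Lay out a synthetic genome with a known operon partition.

    Genes are distributed over ``n_operons`` as evenly as possible and placed
    head-to-tail on ``n_accessions`` accessions: consecutive genes inside an
    operon are separated by exactly ``gap_within`` bp and operon boundaries by
    ``gap_between`` bp. Each operon's lead gene gets a uniform-background
    promoter of ``promoter_length`` bp; when ``motif_pwm`` is given, the
    selected operons (a fraction or an explicit id list) receive one motif
    instance (sampled from the PWM, or its consensus when ``plant_consensus``)
    at a recorded 0-based offset.
    """
    if n_operons > n_genes:
        raise ValueError("n_operons must be <= n_genes")
    if gap_within < 0 or gap_between < 0:
        raise ValueError("gaps must be non-negative")
    if gap_within >= gap_between:
        raise ValueError("gap_within must be < gap_between")
    rng = rng_from(seed, "genome")

    sizes = np.full(n_operons, n_genes // n_operons)
    sizes[: n_genes % n_operons] += 1

    rows = []
    operons: dict[str, list[str]] = {}
    per_acc = int(np.ceil(n_operons / n_accessions))
    gi = 0
    for op in range(n_operons):
        acc = f"acc_{op // per_acc + 1}"
        acc_ordinal = op % per_acc
        if acc_ordinal == 0:
            pos = 1001  # leave room for the upstream promoter
        else:
            pos = rows[-1]["end"] + gap_between + 1
        op_id = f"{acc}_op{acc_ordinal + 1:03d}"
        members = []
        for j in range(sizes[op]):
            if j > 0:
                pos = rows[-1]["end"] + gap_within + 1
            gid = f"g{gi:04d}"
            rows.append(
                {
                    "gene_id": gid,
                    "accession": acc,
                    "start": pos,
                    "end": pos + gene_length - 1,
                    "strand": "+",
                    "operon_id": op_id,
                }
            )
            members.append(gid)
            gi += 1
        operons[op_id] = members

    genes = pd.DataFrame(rows)

    # Promoters for lead genes; optionally plant a motif instance.
    if isinstance(motif_operons, float):
        n_plant = int(round(motif_operons * n_operons))
        planted_ops = list(rng.choice(sorted(operons), size=n_plant, replace=False))
    else:
        planted_ops = list(motif_operons)
    promoters: dict[str, str] = {}
    site_positions: dict[str, int] = {}
    for op_id, members in operons.items():
        lead = members[0]
        seq = _random_sequence(rng, promoter_length)
        if motif_pwm is not None and op_id in planted_ops:
            w = motif_pwm.shape[0]
            offset = int(rng.integers(0, promoter_length - w + 1))
            site = _sample_site(motif_pwm, rng, plant_consensus)
            seq = seq[:offset] + site + seq[offset + w :]
            site_positions[lead] = offset
        promoters[lead] = seq

    return GenomeTruth(
        genes=genes,
        promoters=promoters,
        operons=operons,
        planted_site_positions=site_positions,
        motif_pwm=motif_pwm,
        seed=seed,
    )


def generate_trn_table(
    truth: GroundTruth,
    overlap_fraction: float = 1.0,
    extra_genes: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Derive a draft TRN table from planted modules with controlled overlap.

    For each planted module, the emitted regulon keeps
    ``round(overlap_fraction * module size)`` member genes plus
    ``extra_genes`` random non-members, so downstream recall values are known
    by construction. Returns a two-column (regulator, gene) table.
    """
    if not (0.0 <= overlap_fraction <= 1.0):
        raise ValueError(f"overlap_fraction must be in [0, 1], got {overlap_fraction}")
    if not truth.regulon_labels:
        raise ValueError("ground truth has no planted modules")
    rng = rng_from(seed, "trn")
    universe = list(truth.module_weights.index)
    rows = []
    for regulator in sorted(truth.regulon_labels):
        members = sorted(truth.regulon_labels[regulator])
        n_keep = int(round(overlap_fraction * len(members)))
        kept = list(rng.choice(members, size=n_keep, replace=False))
        non_members = [g for g in universe if g not in truth.regulon_labels[regulator]]
        extras = list(rng.choice(non_members, size=min(extra_genes, len(non_members)), replace=False))
        for g in sorted(kept) + sorted(extras):
            rows.append({"regulator": regulator, "gene": g})
    return pd.DataFrame(rows, columns=["regulator", "gene"])
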