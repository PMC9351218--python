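"""Expression tensors and the channel-separated convolutional feature branch.

Time-course expression data comes with two experimental conditions (e.g. an
untreated control culture and an oxidant-exposed one) measured in replicate
at a handful of timepoints.  Per protein the values are arranged into a
``(condition, replicate, timestep)`` tensor; the branch treats the two
conditions as separate channels (depthwise part), convolves each over time
with the replicates as input channels, then mixes the two condition streams
with a kernel-size-1 pointwise convolution before pooling down to a
16-dimensional feature.

Replicate series of the same condition are strongly correlated (Pearson
correlation typically 0.6-0.9 on real microarray time courses) while series
from different conditions correlate only weakly (0.1-0.6);
:func:`replicate_condition_pcc_profile` reports these diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import ExpressionTable
from .nn import batch_norm_forward, conv1d_forward, dense_forward

__all__ = [
    "ExpressionTensorSet",
    "BranchWeights",
    "pearson_cc",
    "aggregate_probes",
    "assemble_expression_tensor",
    "replicate_condition_pcc_profile",
    "conv1d_forward",
    "batch_norm_forward",
    "expression_branch_forward",
]


@dataclass
class ExpressionTensorSet:
    """Aligned per-protein expression tensors.

    ``values`` has shape ``(n_proteins, n_conditions, n_replicates,
    n_timesteps)``; proteins absent from the source table are all-zero with
    ``presence`` False.
    """

    proteins: list[str]
    values: np.ndarray
    presence: np.ndarray  # bool, (n_proteins,)
    conditions: list[str]
    replicates: list[int]
    timepoints: list[float]


def pearson_cc(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation coefficient between two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("inputs must be equal-length vectors of length >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0.0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def aggregate_probes(
    table: ExpressionTable,
    probe_to_gene: Mapping[str, str],
    method: str = "max_mean_probe",
) -> ExpressionTable:
    """Collapse multiple probes per gene to a single row.

    ``max_mean_probe`` (default) keeps, for each gene, the full row of the
    probe whose mean expression across all samples is maximal.  The
    alternative reading ``per_sample_max`` takes, per sample, the maximum
    over the gene's probes; it is exposed for comparison without endorsing
    either interpretation.  Probes without a mapping are dropped.
    """
    if not probe_to_gene:
        raise ValueError("empty probe-to-gene mapping")
    frame = table.values
    mapped = [p for p in frame.index if p in probe_to_gene]
    if method == "max_mean_probe":
        rows: dict[str, pd.Series] = {}
        means: dict[str, float] = {}
        for probe in mapped:
            gene = probe_to_gene[probe]
            m = frame.loc[probe].mean(skipna=True)
            if gene not in rows or m > means[gene]:
                rows[gene] = frame.loc[probe]
                means[gene] = m
        new = pd.DataFrame(rows).T
    elif method == "per_sample_max":
        sub = frame.loc[mapped]
        genes = pd.Series([probe_to_gene[p] for p in mapped], index=sub.index)
        new = sub.groupby(genes).max()
    else:
        raise ValueError(f"unknown aggregation method {method!r}")
    new.index.name = frame.index.name
    return ExpressionTable(values=new, annotations=table.annotations)


def assemble_expression_tensor(
    table: ExpressionTable,
    proteins: Sequence[str],
    shape: tuple[int, int, int],
    conditions: Sequence[str] | None = None,
    replicate_selection: Sequence[int] | None = None,
    pad_to: int | None = None,
) -> ExpressionTensorSet:
    """Place annotated samples into ``(condition, replicate, timestep)`` slots.

    Timepoints are ranked ascending; timesteps beyond the available data are
    zero-padded at the tail up to ``pad_to``.  Missing cells and proteins
    absent from the table become zeros (absent proteins get ``presence``
    False).
    """
    n_cond, n_rep, n_time = shape
    anns = table.annotations
    all_conditions = sorted({a.condition for a in anns.values()})
    conditions = list(conditions) if conditions is not None else all_conditions
    if len(conditions) != n_cond:
        raise ValueError(f"{n_cond} conditions requested but got {conditions}")
    available_reps = sorted({a.replicate for a in anns.values()})
    reps = list(replicate_selection) if replicate_selection is not None else available_reps[:n_rep]
    missing_reps = [r for r in reps if r not in available_reps]
    if missing_reps:
        raise ValueError(
            f"requested replicates {missing_reps} not in annotations; available: {available_reps}"
        )
    timepoints = sorted({a.timepoint_min for a in anns.values()})[:n_time]
    pad_to = pad_to or n_time
    if pad_to < len(timepoints):
        raise ValueError("pad_to smaller than the number of observed timepoints")

    slot = {}  # (condition, replicate, time-rank) -> sample name
    for sample, a in anns.items():
        if a.condition in conditions and a.replicate in reps and a.timepoint_min in timepoints:
            slot[(conditions.index(a.condition), reps.index(a.replicate), timepoints.index(a.timepoint_min))] = sample

    values = np.zeros((len(proteins), n_cond, n_rep, pad_to))
    frame = table.values
    present_ids = frame.index
    presence = np.array([p in present_ids for p in proteins])
    sub = frame.reindex(proteins)
    for (c, r, t), sample in slot.items():
        col = sub[sample].to_numpy(dtype=float)
        values[:, c, r, t] = np.nan_to_num(col, nan=0.0)
    return ExpressionTensorSet(
        proteins=list(proteins),
        values=values,
        presence=presence,
        conditions=conditions,
        replicates=reps,
        timepoints=[float(t) for t in timepoints],
    )


def replicate_condition_pcc_profile(tensors: ExpressionTensorSet) -> dict:
    """Pairwise Pearson correlations within and across conditions.

    For each present protein, replicate pairs of the same condition are
    correlated over the time course, and replicate pairs across the two
    conditions likewise.  Constant series are skipped and counted.
    """
    vals = tensors.values[tensors.presence]
    if vals.shape[0] == 0:
        raise ValueError("no protein with measured expression")
    n_cond, n_rep = vals.shape[1], vals.shape[2]
    within, across = [], []
    skipped = 0
    for prot in vals:
        try:
            for c in range(n_cond):
                for r1 in range(n_rep):
                    for r2 in range(r1 + 1, n_rep):
                        within.append(pearson_cc(prot[c, r1], prot[c, r2]))
            for c1 in range(n_cond):
                for c2 in range(c1 + 1, n_cond):
                    for r1 in range(n_rep):
                        for r2 in range(n_rep):
                            across.append(pearson_cc(prot[c1, r1], prot[c2, r2]))
        except ValueError:
            skipped += 1
            continue
    within_a, across_a = np.array(within), np.array(across)
    def q(a):
        return {} if a.size == 0 else {
            "median": float(np.median(a)),
            "q25": float(np.quantile(a, 0.25)),
            "q75": float(np.quantile(a, 0.75)),
        }
    return {
        "replicate_pcc": within_a,
        "cross_condition_pcc": across_a,
        "replicate_summary": q(within_a),
        "cross_condition_summary": q(across_a),
        "n_skipped_constant": skipped,
    }


@dataclass
class BranchWeights:
    """All parameters of the expression branch, one conv/BN stack per condition.

    Shapes for the default layout (T timesteps, 3 replicates, 64 filters):
    ``conv_kernels[c]`` is ``(3, 3, 64)``, pointwise ``(1, 128, 64)``, dense
    ``(64, 16)``.
    """

    conv_kernels: list[np.ndarray]
    conv_biases: list[np.ndarray]
    bn_gamma: list[np.ndarray]
    bn_beta: list[np.ndarray]
    bn_mean: list[np.ndarray]
    bn_var: list[np.ndarray]
    bn_eps: float
    pointwise_kernel: np.ndarray
    pointwise_bias: np.ndarray
    dense_weights: np.ndarray
    dense_bias: np.ndarray
    pool: int = 2


def expression_branch_forward(
    tensor: np.ndarray, weights: BranchWeights, mode: str = "infer"
) -> np.ndarray:
    """Forward pass of the expression branch for a batch of tensors.

    ``tensor`` is ``(B, n_cond, n_rep, T)`` (a single ``(n_cond, n_rep, T)``
    tensor is promoted).  Per condition: conv over time with replicates as
    input channels -> batch norm -> max pool (size 2); the condition outputs
    are concatenated along channels, mixed by the pointwise convolution,
    globally max-pooled over time and condensed to 16 ReLU units.
    """
    squeeze = tensor.ndim == 3
    if squeeze:
        tensor = tensor[None]
    n_cond = tensor.shape[1]
    if n_cond != len(weights.conv_kernels):
        raise ValueError("condition count does not match branch weights")
    streams = []
    for c in range(n_cond):
        x = tensor[:, c].transpose(0, 2, 1)  # (B, T, replicates)
        x = conv1d_forward(x, weights.conv_kernels[c], weights.conv_biases[c], activation="relu")
        x, _, _ = batch_norm_forward(
            x,
            weights.bn_gamma[c],
            weights.bn_beta[c],
            eps=weights.bn_eps,
            mode=mode,
            running_mean=weights.bn_mean[c],
            running_var=weights.bn_var[c],
        )
        B, T, F = x.shape
        n = T // weights.pool
        x = x[:, : n * weights.pool, :].reshape(B, n, weights.pool, F).max(axis=2)
        streams.append(x)
    x = np.concatenate(streams, axis=2)
    x = conv1d_forward(x, weights.pointwise_kernel, weights.pointwise_bias, activation="relu")
    x = x.max(axis=1)  # global max pool over time
    out = dense_forward(x, weights.dense_weights, weights.dense_bias, activation="relu")
    return out[0] if squeeze else out
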