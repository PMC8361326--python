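"""Synthetic cohorts of co-topological multi-weight connectomes.

The generator emulates what the classification pipeline consumes: a cohort of
90-node brain networks where every subject shares one binary topology and
carries three edge weightings (FN streamline counts, mean-FA, mean-MD), with a
patient group whose affected edges are shifted by a stated number of
between-subject standard deviations.  The canonical pathological direction is
decreased FA and FN with increased MD in patients.

Randomness is driven by one global seed through a documented splitting scheme
(topology, baselines, noise, jitter are independent sub-streams), so each
ingredient is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .aal import default_node_labels
from .connectome import MultiWeightConnectome, StreamlinePhantom

# Between-subject spread of edge weights at noise_sd = 1, per weight kind.
# FA ~0.04 and MD ~0.03e-3 are realistic inter-subject SDs for single-edge
# mean-FA/mean-MD values; FN spread scales with the edge's baseline count.
FA_SD = 0.04
MD_SD = 0.03e-3
FN_SD_FRACTION = 0.15  # SD = 0.15 * baseline + 0.5 streamlines

# Sub-stream indices of the seed-splitting scheme.
_STREAM_TOPOLOGY, _STREAM_BASELINE, _STREAM_NOISE, _STREAM_JITTER = range(4)


@dataclass
class GroupEffectSpec:
    """Group-difference injected into the patient (+1) group.

    Effects are signed shifts in units of the affected edge's between-subject
    SD, applied to every edge in ``affected_edges`` (1-based (i, j), i < j).
    """

    affected_edges: tuple[tuple[int, int], ...] = ()
    effect_fn: float = 0.0
    effect_fa: float = 0.0
    effect_md: float = 0.0

    def __post_init__(self) -> None:
        edges = []
        for i, j in self.affected_edges:
            if not i < j:
                raise ValueError(f"affected edge ({i}, {j}) must have i < j")
            edges.append((int(i), int(j)))
        self.affected_edges = tuple(edges)


@dataclass
class CohortConfig:
    """Study conditions for one simulated cohort.

    Defaults mirror the reference cohort the pipeline was designed around:
    90 AAL nodes at 25% connection density (typical for deterministic
    tractography networks) and a 51-control / 36-patient split.
    """

    n_nodes: int = 90
    density: float = 0.25
    n_per_group: tuple[int, int] = (51, 36)  # (controls -1, patients +1)
    noise_sd: tuple[float, float, float] = (1.0, 1.0, 1.0)  # (FN, FA, MD)
    effect: GroupEffectSpec = field(default_factory=GroupEffectSpec)
    seed: int = 0
    topology_jitter: float = 0.0  # fraction of edges flipped per subject

    def __post_init__(self) -> None:
        if not 0 < self.density <= 1:
            raise ValueError("density must be in (0, 1]")
        n_pairs = self.n_nodes * (self.n_nodes - 1) // 2
        if round(self.density * n_pairs) < len(self.effect.affected_edges):
            raise ValueError("density too low to host the affected edges")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, stream])))


def sample_topology(n_nodes: int, density: float, seed: int) -> list[tuple[int, int]]:
    """The shared binary support: 1-based pairs, deterministic in the seed."""
    iu, ju = np.triu_indices(n_nodes, k=1)
    n_pairs = len(iu)
    n_edges = max(1, int(round(density * n_pairs)))
    rng = _rng(seed, _STREAM_TOPOLOGY)
    chosen = np.sort(rng.choice(n_pairs, size=n_edges, replace=False))
    return [(int(iu[k]) + 1, int(ju[k]) + 1) for k in chosen]


def generate_cohort(config: CohortConfig) -> list[tuple[MultiWeightConnectome, int]]:
    """Simulate one labelled cohort, controls first, reproducible from the seed."""
    n = config.n_nodes
    edges = sample_topology(n, config.density, config.seed)
    edge_set = set(edges)
    for e in config.effect.affected_edges:
        if e not in edge_set:
            raise ValueError(
                f"affected edge {e} is not in the sampled topology; raise the "
                "density or pick edges from sample_topology()"
            )
    n_edges = len(edges)
    rng_base = _rng(config.seed, _STREAM_BASELINE)
    # Edge-specific baselines in physically plausible ranges.
    base_fn = np.exp(rng_base.normal(3.0, 1.0, size=n_edges))  # median ~20 streamlines
    base_fa = rng_base.uniform(0.25, 0.75, size=n_edges)
    base_md = np.clip(rng_base.normal(0.7e-3, 0.05e-3, size=n_edges), 1e-4, None)

    sd_fn = config.noise_sd[0] * (FN_SD_FRACTION * base_fn + 0.5)
    sd_fa = np.full(n_edges, config.noise_sd[1] * FA_SD)
    sd_md = np.full(n_edges, config.noise_sd[2] * MD_SD)

    affected = np.array([e in set(config.effect.affected_edges) for e in edges])
    shift_fn = np.where(affected, config.effect.effect_fn * sd_fn, 0.0)
    shift_fa = np.where(affected, config.effect.effect_fa * sd_fa, 0.0)
    shift_md = np.where(affected, config.effect.effect_md * sd_md, 0.0)

    rng_noise = _rng(config.seed, _STREAM_NOISE)
    rng_jitter = _rng(config.seed, _STREAM_JITTER)
    node_labels = default_node_labels(n)
    idx = (np.array([e[0] - 1 for e in edges]), np.array([e[1] - 1 for e in edges]))

    cohort: list[tuple[MultiWeightConnectome, int]] = []
    for label, n_group in zip((-1, 1), config.n_per_group):
        for _ in range(n_group):
            z = rng_noise.standard_normal((3, n_edges))
            fn_e = base_fn + sd_fn * z[0]
            fa_e = base_fa + sd_fa * z[1]
            md_e = base_md + sd_md * z[2]
            if label == 1:
                fn_e = fn_e + shift_fn
                fa_e = fa_e + shift_fa
                md_e = md_e + shift_md
            fn_e = np.maximum(np.round(fn_e), 1.0)
            fa_e = np.clip(fa_e, 1e-3, 1.0)
            md_e = np.clip(md_e, 1e-5, None)

            keep = np.ones(n_edges, dtype=bool)
            extra: list[tuple[int, int]] = []
            if config.topology_jitter > 0:
                keep, extra = _jitter_support(
                    n, edges, config.topology_jitter, rng_jitter
                )
            fn = np.zeros((n, n)); fa = np.zeros((n, n)); md = np.zeros((n, n))
            fn[idx] = fn_e * keep; fa[idx] = fa_e * keep; md[idx] = md_e * keep
            for (i, j) in extra:
                fn[i - 1, j - 1] = max(1.0, float(np.round(np.exp(rng_jitter.normal(3.0, 1.0)))))
                fa[i - 1, j - 1] = rng_jitter.uniform(0.25, 0.75)
                md[i - 1, j - 1] = float(np.clip(rng_jitter.normal(0.7e-3, 0.05e-3), 1e-4, None))
            fn = fn + fn.T; fa = fa + fa.T; md = md + md.T
            cohort.append((
                MultiWeightConnectome(fn=fn, fa=fa, md=md, node_labels=node_labels),
                label,
            ))
    return cohort


def _jitter_support(n_nodes, edges, fraction, rng):
    """Drop/add a stated fraction of edges for one subject's topology."""
    n_edges = len(edges)
    n_flip = int(round(fraction * n_edges))
    keep = np.ones(n_edges, dtype=bool)
    if n_flip:
        keep[rng.choice(n_edges, size=n_flip, replace=False)] = False
    edge_set = set(edges)
    iu, ju = np.triu_indices(n_nodes, k=1)
    absent = [(int(i) + 1, int(j) + 1) for i, j in zip(iu, ju)
              if (int(i) + 1, int(j) + 1) not in edge_set]
    extra = []
    if n_flip and absent:
        picks = rng.choice(len(absent), size=min(n_flip, len(absent)), replace=False)
        extra = [absent[k] for k in picks]
    return keep, extra


def make_reference_config(seed: int, n_per_group: tuple[int, int] = (40, 40),
                          n_affected: int = 12, effect_md: float = 1.5,
                          effect_fa: float = 0.0, effect_fn: float = 0.0,
                          n_nodes: int = 90, density: float = 0.25) -> CohortConfig:
    """The seeded recovery condition: an MD-only 1.5 SD effect on 12 edges.

    Affected edges are drawn (reproducibly) from the topology the same seed
    will generate, so the support invariant holds by construction.
    """
    edges = sample_topology(n_nodes, density, seed)
    rng = _rng(seed, 17)  # dedicated stream for the affected-edge draw
    picks = rng.choice(len(edges), size=n_affected, replace=False)
    affected = tuple(edges[k] for k in np.sort(picks))
    return CohortConfig(
        n_nodes=n_nodes, density=density, n_per_group=n_per_group,
        effect=GroupEffectSpec(affected_edges=affected, effect_fn=effect_fn,
                               effect_fa=effect_fa, effect_md=effect_md),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Streamline phantoms
# ---------------------------------------------------------------------------

def generate_phantom(n_regions: int,
                     n_streamlines_per_pair: dict[tuple[int, int], int],
                     seed: int = 0) -> StreamlinePhantom:
    """A small synthetic labelled volume realizing exact endpoint-pair counts.

    Regions are contiguous slabs along the x-axis separated by one background
    plane; FA/MD fields vary smoothly; streamlines are straight voxel lines
    from a voxel inside region i to a voxel inside region j.
    """
    if n_regions < 2:
        raise ValueError("need at least two regions")
    for (i, j), c in n_streamlines_per_pair.items():
        if not (1 <= i < j <= n_regions):
            raise ValueError(f"pair ({i}, {j}) invalid for {n_regions} regions")
        if c < 0:
            raise ValueError("streamline counts must be >= 0")
    slab = 3
    nx = n_regions * (slab + 1)
    shape = (nx, 5, 5)
    lab = np.zeros(shape, dtype=int)
    for r in range(1, n_regions + 1):
        x0 = (r - 1) * (slab + 1)
        lab[x0:x0 + slab, :, :] = r
    x, y, z = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    fa = np.clip(0.45 + 0.2 * np.sin(x / 2.0) + 0.1 * np.cos(y + z), 0.05, 0.95)
    md = 0.7e-3 * (1.0 + 0.15 * np.sin(x / 3.0 + y / 2.0))

    rng = np.random.default_rng(np.random.SeedSequence([seed, 99]))
    streams: list[np.ndarray] = []
    for (i, j), c in sorted(n_streamlines_per_pair.items()):
        for _ in range(c):
            start = _random_region_voxel(lab, i, rng)
            end = _random_region_voxel(lab, j, rng)
            n_steps = int(np.abs(end - start).max()) + 1
            line = np.rint(np.linspace(start, end, max(n_steps, 2))).astype(int)
            keep = np.ones(len(line), dtype=bool)
            keep[1:] = np.any(line[1:] != line[:-1], axis=1)
            streams.append(line[keep])
    return StreamlinePhantom(label_volume=lab, fa_volume=fa, md_volume=md,
                             streamlines=streams)


def _random_region_voxel(lab, region, rng):
    coords = np.argwhere(lab == region)
    return coords[rng.integers(len(coords))]
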