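"""Seeded synthetic-data generators with known ground truth.

Three generators emulate the three data modalities of the ploidy study:

* :func:`simulate_confocal_scene` — 3-D DAPI + marker-channel stacks of
  ellipsoidal nuclei whose expected integrated DNA-stain signal is exactly
  proportional to ploidy class (2n/4n/8n), under Poisson shot noise and
  Gaussian read noise.
* :func:`simulate_flow_events` — DNA-content cytometry event tables with
  2n/4n/8n peaks of given coefficient of variation, additive-area doublets
  and sub-G1 debris.
* :func:`simulate_counts` — UMI count matrices for a fibroblast /
  endothelial / lymphocyte mixture with marker-gene enrichment,
  negative-binomial noise, mitochondrial fractions, and planted QC failures.

Every generator takes a seed and is bit-reproducible.  Each returns a
ground-truth table so that downstream inference can be scored by parameter
recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, sparse

from .imaging import ImageStack

MARKER_NAMES = ("ckit", "tryptase", "cardiomyocyte")


def largest_remainder(fractions, n: int) -> np.ndarray:
    """Integer class counts summing to n, closest to n * fractions."""
    fr = np.asarray(fractions, dtype=float)
    base = np.floor(fr * n).astype(int)
    rem = fr * n - base
    short = n - base.sum()
    base[np.argsort(rem)[::-1][:short]] += 1
    return base

#: expression-share of mitochondrial genes in healthy cells: Beta(6, 194),
#: mean 3 %, essentially never above the 10 % QC cut-off.
_MITO_BETA = (6.0, 194.0)


# --------------------------------------------------------------------------
# confocal scenes
# --------------------------------------------------------------------------

@dataclass
class Nucleus:
    """Axis-aligned (optionally z-rotated) ellipsoidal nucleus.

    ``center_um`` and ``semi_axes_um`` are (z, y, x) in micrometres;
    ``ploidy`` is the DNA-content class in {2, 4, 8}.
    """

    center_um: tuple[float, float, float]
    semi_axes_um: tuple[float, float, float] = (2.5, 3.0, 3.0)
    ploidy: int = 2
    cell_type: str = "ccic"
    markers: dict[str, bool] = field(default_factory=dict)
    rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.ploidy not in (2, 4, 8):
            raise ValueError(f"ploidy must be 2, 4 or 8, got {self.ploidy}")
        if any(a <= 0 for a in self.semi_axes_um):
            raise ValueError("semi-axes must be positive")
        self.markers = {m: bool(self.markers.get(m, False)) for m in MARKER_NAMES}


@dataclass
class SceneSpec:
    """Full description of one synthetic confocal z-stack.

    ``signal_model='density'`` keeps nuclear volume fixed and scales voxel
    signal density with ploidy (the regime in which a widest-plane statistic
    is exactly proportional to DNA content); ``'volume'`` keeps density fixed
    and scales nuclear volume with ploidy instead.  ``photon_scale`` is the
    expected photon count per voxel of a 2n nucleus.
    """

    shape: tuple[int, int, int] = (21, 256, 256)
    voxel_size_um: tuple[float, float, float] = (0.426, 0.071, 0.071)
    nuclei: list[Nucleus] = field(default_factory=list)
    signal_model: str = "density"
    photon_scale: float = 100.0
    background_rate: float = 5.0
    read_noise_sd: float = 2.0
    marker_scale: float = 60.0
    marker_channels: tuple[str, ...] = MARKER_NAMES
    blur_sigma_px: float = 0.0
    noiseless: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.signal_model not in ("density", "volume"):
            raise ValueError("signal_model must be 'density' or 'volume'")
        if self.photon_scale <= 0:
            raise ValueError("photon_scale must be positive")
        ext = np.asarray(self.shape) * np.asarray(self.voxel_size_um)
        for i, nuc in enumerate(self.nuclei):
            semi = np.asarray(nuc.semi_axes_um) * self._scale(nuc)
            c = np.asarray(nuc.center_um)
            if np.any(c - semi < 0) or np.any(c + semi > ext):
                raise ValueError(f"nucleus {i} extends outside the grid")
        self._check_overlap()

    def _scale(self, nuc: Nucleus) -> float:
        """Linear size factor: (ploidy/2)^(1/3) in volume mode, else 1."""
        return (nuc.ploidy / 2.0) ** (1.0 / 3.0) if self.signal_model == "volume" else 1.0

    def _check_overlap(self) -> None:
        # conservative bounding-sphere test; scenes are non-overlapping by contract
        centers = np.array([n.center_um for n in self.nuclei], dtype=float)
        radii = np.array(
            [max(n.semi_axes_um) * self._scale(n) for n in self.nuclei], dtype=float
        )
        for i in range(len(self.nuclei)):
            d = np.linalg.norm(centers[i + 1:] - centers[i], axis=1)
            if np.any(d < radii[i] + radii[i + 1:]):
                j = int(np.argmax(d < radii[i] + radii[i + 1:])) + i + 1
                raise ValueError(f"nuclei {i} and {j} overlap")


def _ellipsoid_voxels(
    shape: tuple[int, int, int],
    voxel: tuple[float, float, float],
    center: np.ndarray,
    semi: np.ndarray,
    rotation_deg: float,
) -> tuple[tuple[np.ndarray, ...], int]:
    """Indices of voxels whose centres fall inside the (rotated) ellipsoid."""
    lo = np.maximum(((center - semi) / voxel - 1).astype(int), 0)
    hi = np.minimum(((center + semi) / voxel + 2).astype(int), shape)
    ax = [(np.arange(lo[d], hi[d]) + 0.5) * voxel[d] - center[d] for d in range(3)]
    dz, dy, dx = np.meshgrid(*ax, indexing="ij")
    if rotation_deg:
        th = np.deg2rad(rotation_deg)
        dy, dx = dy * np.cos(th) - dx * np.sin(th), dy * np.sin(th) + dx * np.cos(th)
    inside = (dz / semi[0]) ** 2 + (dy / semi[1]) ** 2 + (dx / semi[2]) ** 2 <= 1.0
    zz, yy, xx = np.nonzero(inside)
    return (zz + lo[0], yy + lo[1], xx + lo[2]), int(inside.sum())


def simulate_confocal_scene(
    spec: SceneSpec,
) -> tuple[ImageStack, np.ndarray, pd.DataFrame]:
    """Render a scene into (stack, label volume, ground-truth table).

    The DAPI channel is Poisson(signal + background) plus Gaussian read
    noise, clipped at zero.  Per nucleus the *expected* integrated photon
    count equals ``(ploidy / 2) * photon_scale * V2n`` exactly in both
    signal models, where ``V2n`` is the analytic 2n ellipsoid volume in
    voxel units — voxel densities are normalised to enforce this despite
    rasterisation.  Marker channels carry signal only inside flagged nuclei.
    """
    rng = np.random.default_rng(spec.seed)
    voxel = np.asarray(spec.voxel_size_um)
    signal = np.zeros(spec.shape, dtype=float)
    labels = np.zeros(spec.shape, dtype=np.int32)
    marker_sig = {m: np.zeros(spec.shape, dtype=float) for m in spec.marker_channels}
    truth_rows = []

    for nid, nuc in enumerate(spec.nuclei, start=1):
        center = np.asarray(nuc.center_um, dtype=float)
        semi2n = np.asarray(nuc.semi_axes_um, dtype=float)
        semi = semi2n * spec._scale(nuc)
        idx, nvox = _ellipsoid_voxels(spec.shape, voxel, center, semi, nuc.rotation_deg)
        if nvox == 0:
            raise ValueError(f"nucleus {nid} covers no voxels at this resolution")
        # analytic 2n volume in voxel units; normalising the voxel density to
        # it makes the expected integral exactly (ploidy/2) x the 2n total in
        # both signal models, independent of rasterisation phase
        v2n = (4.0 / 3.0) * np.pi * np.prod(semi2n) / np.prod(voxel)
        total = spec.photon_scale * (nuc.ploidy / 2.0) * v2n
        density = total / nvox
        signal[idx] += density
        labels[idx] = nid
        for m in spec.marker_channels:
            if nuc.markers[m]:
                marker_sig[m][idx] += spec.marker_scale
        truth_rows.append(
            {
                "nucleus_id": nid,
                "ploidy": nuc.ploidy,
                "true_integrated_signal": total,
                "cell_type": nuc.cell_type,
                **{m: nuc.markers[m] for m in MARKER_NAMES},
            }
        )

    def render(expected: np.ndarray) -> np.ndarray:
        img = expected + spec.background_rate
        if spec.blur_sigma_px > 0:
            img = ndimage.gaussian_filter(img, spec.blur_sigma_px)
        if spec.noiseless:
            return img
        out = rng.poisson(img).astype(float)
        if spec.read_noise_sd > 0:
            out += rng.normal(0.0, spec.read_noise_sd, size=out.shape)
        return np.clip(out, 0.0, None)

    channels = {"dapi": render(signal)}
    for m in spec.marker_channels:
        channels[m] = render(marker_sig[m])

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "nucleus_id", "ploidy", "true_integrated_signal", "cell_type",
            *MARKER_NAMES,
        ],
    )
    stack = ImageStack(channels=channels, voxel_size_um=tuple(voxel))
    return stack, labels, truth


def layout_scene(
    ploidies: list[int],
    markers: list[dict[str, bool]] | None = None,
    cell_types: list[str] | None = None,
    pitch_um: float = 8.5,
    semi_axes_um: tuple[float, float, float] = (2.5, 3.0, 3.0),
    jitter_um: float = 0.4,
    n_slices: int = 21,
    seed: int = 0,
    **spec_kwargs,
) -> SceneSpec:
    """Place nuclei on a jittered square grid and return a ready SceneSpec.

    A convenience for recovery experiments: guarantees non-overlap and
    in-bounds placement for any nucleus count.
    """
    rng = np.random.default_rng(seed)
    n = len(ploidies)
    markers = markers or [{} for _ in range(n)]
    cell_types = cell_types or ["ccic"] * n
    ncol = int(np.ceil(np.sqrt(n)))
    nrow = int(np.ceil(n / ncol))
    voxel = spec_kwargs.get("voxel_size_um", (0.426, 0.071, 0.071))
    # worst-case linear size factor is (8/2)^(1/3) in volume mode
    size_factor = 4 ** (1 / 3) if spec_kwargs.get("signal_model") == "volume" else 1.0
    max_r = max(semi_axes_um[1:]) * size_factor
    pitch_um = max(pitch_um, 2 * max_r + 2 * jitter_um + 0.3)
    margin = max_r + jitter_um + 0.5
    ext_y = (nrow - 1) * pitch_um + 2 * margin
    ext_x = (ncol - 1) * pitch_um + 2 * margin
    shape = (
        n_slices,
        int(np.ceil(ext_y / voxel[1])) + 1,
        int(np.ceil(ext_x / voxel[2])) + 1,
    )
    z_mid = n_slices * voxel[0] / 2.0
    nuclei = []
    for i, p in enumerate(ploidies):
        r, c = divmod(i, ncol)
        jy, jx = rng.uniform(-jitter_um, jitter_um, size=2)
        nuclei.append(
            Nucleus(
                center_um=(z_mid, margin + r * pitch_um + jy, margin + c * pitch_um + jx),
                semi_axes_um=semi_axes_um,
                ploidy=int(p),
                cell_type=cell_types[i],
                markers=markers[i],
            )
        )
    return SceneSpec(shape=shape, nuclei=nuclei, seed=int(rng.integers(2**31)),
                     **spec_kwargs)


# --------------------------------------------------------------------------
# flow cytometry
# --------------------------------------------------------------------------

@dataclass
class FlowSimParams:
    """Parameters of the synthetic DNA-content cytometry experiment.

    ``fractions`` are the true (2n, 4n, >4n) singlet class fractions; the 4n
    peak sits at twice and the >4n peak at four times the 2n channel
    position.  Doublets are sums of two singlet areas with the width of one
    singlet; debris is uniform below the 2n peak.
    """

    n_events: int = 10_000
    fractions: tuple[float, float, float] = (0.5451, 0.418, 0.0369)
    mean_2n: float = 200.0
    cv: float = 0.05
    doublet_rate: float = 0.05
    debris_rate: float = 0.02
    width_ratio: float = 10.0
    width_cv: float = 0.05
    s_phase_bridge: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        fr = np.asarray(self.fractions, dtype=float)
        if fr.min() < 0 or fr.max() > 1 or abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must lie in [0,1] and sum to 1")
        if self.cv <= 0:
            raise ValueError("cv must be positive")
        for r in (self.doublet_rate, self.debris_rate, self.s_phase_bridge):
            if not 0 <= r < 1:
                raise ValueError("rates must lie in [0, 1)")


_CLASS_NAMES = np.array(["2n", "4n", ">4n"])
_CLASS_MULT = np.array([1.0, 2.0, 4.0])


def simulate_flow_events(params: FlowSimParams) -> pd.DataFrame:
    """Simulate an event table with columns ``area, width, true_class``.

    ``true_class`` is one of ``2n, 4n, >4n, doublet, debris, s_phase``;
    class peaks are lognormal with unit mean and the requested CV.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_events
    sigma = np.sqrt(np.log1p(params.cv**2))

    def singlet_areas(k: int) -> np.ndarray:
        cls = rng.choice(3, size=k, p=params.fractions)
        spread = rng.lognormal(-sigma**2 / 2.0, sigma, size=k)
        return _CLASS_MULT[cls] * params.mean_2n * spread, cls

    def singlet_width(area: np.ndarray) -> np.ndarray:
        return area / params.width_ratio * (
            1.0 + rng.normal(0.0, params.width_cv, size=area.shape)
        )

    u = rng.random(n)
    p_dbl, p_deb = params.doublet_rate, params.debris_rate
    p_s = params.s_phase_bridge
    kind = np.select(
        [u < p_dbl, u < p_dbl + p_deb, u < p_dbl + p_deb + p_s],
        ["doublet", "debris", "s_phase"],
        default="singlet",
    )
    area = np.empty(n)
    width = np.empty(n)
    true_class = np.empty(n, dtype=object)

    m = kind == "singlet"
    a, cls = singlet_areas(int(m.sum()))
    area[m], width[m], true_class[m] = a, singlet_width(a), _CLASS_NAMES[cls]

    m = kind == "doublet"
    k = int(m.sum())
    a1, _ = singlet_areas(k)
    a2, _ = singlet_areas(k)
    area[m], width[m], true_class[m] = a1 + a2, singlet_width(a1), "doublet"

    m = kind == "debris"
    k = int(m.sum())
    a = rng.uniform(0.05, 0.28, size=k) * params.mean_2n
    area[m], width[m], true_class[m] = a, singlet_width(a), "debris"

    m = kind == "s_phase"
    k = int(m.sum())
    a = rng.uniform(1.05, 1.95, size=k) * params.mean_2n
    area[m], width[m], true_class[m] = a, singlet_width(a), "s_phase"

    width = np.clip(width, 1e-9, None)
    return pd.DataFrame({"area": area, "width": width, "true_class": true_class})


# --------------------------------------------------------------------------
# UMI counts
# --------------------------------------------------------------------------

DEFAULT_MARKERS: dict[str, tuple[str, ...]] = {
    "fibroblast": ("Col3a1", "Mmp2", "Dcn", "Thbs1"),
    "endothelial": ("Pecam1", "Cdh5", "Cd36", "Tcf15", "Gpihbp1"),
    "lymphocyte": ("Cd3e",),
}

#: mm10 mitochondrial protein-coding genes (prefix "mt-")
MITO_GENES = (
    "mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Atp8", "mt-Atp6", "mt-Co3",
    "mt-Nd3", "mt-Nd4l", "mt-Nd4", "mt-Nd5", "mt-Nd6", "mt-Cytb",
)


@dataclass
class CountsSimParams:
    """Parameters of the synthetic droplet scRNA-seq experiment.

    Cells belong to three types (default proportions: the diploid
    fresh-isolate mixture of fibroblast 69 %, endothelial 29 %, lymphocyte
    2 %).  Marker genes are enriched ``marker_fold``-fold in their own type.
    Counts are negative-binomial; a ``lowq_fraction`` of cells is planted to
    fail QC, half by tiny library (low genes detected) and half by a 25 %
    mitochondrial expression share.
    """

    n_cells: int = 1000
    type_proportions: dict[str, float] = field(
        default_factory=lambda: {"fibroblast": 0.69, "endothelial": 0.29, "lymphocyte": 0.02}
    )
    markers: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_MARKERS)
    )
    n_genes: int = 8000
    marker_base_mean: float = 1.0
    marker_fold: float = 30.0
    n_program_genes: int = 150
    program_fold: float = 4.0
    lib_size_mean: float = 6000.0
    lib_size_cv: float = 0.3
    dispersion: float = 0.5
    mito_fraction_high: float = 0.25
    lowq_fraction: float = 0.05
    lowq_lib_scale: float = 0.06
    n_variable_planted: int = 0
    variable_fold: float = 20.0
    exact_proportions: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        props = np.asarray(list(self.type_proportions.values()), dtype=float)
        if abs(props.sum() - 1.0) > 1e-9 or props.min() < 0:
            raise ValueError("type proportions must be non-negative and sum to 1")
        seen: dict[str, str] = {}
        for t, genes in self.markers.items():
            for g in genes:
                if g in seen:
                    raise ValueError(
                        f"marker gene {g!r} listed for both {seen[g]!r} and {t!r}"
                    )
                seen[g] = t
        if not 0 <= self.lowq_fraction < 1:
            raise ValueError("lowq_fraction must lie in [0, 1)")


@dataclass
class CountMatrix:
    """Genes x cells sparse UMI matrix with names and optional group labels."""

    counts: sparse.csr_matrix
    genes: list[str]
    barcodes: list[str]
    groups: pd.Series | None = None  # per-cell ploidy group (e.g. 2N_F / 4N_F)

    def __post_init__(self) -> None:
        self.counts = sparse.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.barcodes)):
            raise ValueError("matrix shape does not match gene/barcode lists")
        if self.counts.nnz and (self.counts.data < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_anndata(self):
        """Cells x genes AnnData view (the transcriptomics-ecosystem layout)."""
        import anndata

        ad = anndata.AnnData(X=self.counts.T.tocsr())
        ad.obs_names = list(self.barcodes)
        ad.var_names = list(self.genes)
        if self.groups is not None:
            ad.obs["group"] = self.groups.values
        return ad


def simulate_counts(params: CountsSimParams) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate a UMI matrix plus a truth table.

    Truth columns: ``barcode, cell_type, planted_fail`` (one of ``none,
    low_genes, high_mito``) and ``lib_size, mito_target``.
    """
    rng = np.random.default_rng(params.seed)
    types = list(params.type_proportions)
    probs = np.asarray(list(params.type_proportions.values()))
    n = params.n_cells
    if params.exact_proportions:
        cell_type = np.repeat(np.arange(len(types)), largest_remainder(probs, n))
        rng.shuffle(cell_type)
    else:
        cell_type = rng.choice(len(types), size=n, p=probs)

    marker_genes = [g for t in types for g in params.markers.get(t, ())]
    n_bg = params.n_genes - len(marker_genes) - len(MITO_GENES)
    if n_bg < 1:
        raise ValueError("n_genes too small for marker + mitochondrial genes")
    genes = marker_genes + list(MITO_GENES) + [f"Gene{i:05d}" for i in range(n_bg)]
    gene_idx = {g: i for i, g in enumerate(genes)}
    G = len(genes)

    # relative expression weights of non-mito genes (lognormal background)
    base_w = np.zeros(G)
    bg_slice = slice(len(marker_genes) + len(MITO_GENES), G)
    base_w[bg_slice] = rng.lognormal(0.0, 1.2, n_bg)
    for g in marker_genes:
        base_w[gene_idx[g]] = params.marker_base_mean * np.mean(base_w[bg_slice])
    # planted highly variable genes: folded up in a random half of cells;
    # base expression spread over a moderate lognormal so the planted set
    # does not cluster in (and so dominate) a single mean-expression bin
    hv_genes = [f"Gene{i:05d}" for i in range(params.n_variable_planted)]
    if hv_genes:
        base_w[[gene_idx[g] for g in hv_genes]] = rng.lognormal(
            0.6, 0.8, len(hv_genes)
        )
    hv_half = rng.random(n) < 0.5

    # per-type weight vectors: markers strongly enriched in their own type,
    # plus a broader per-type expression program (disjoint background gene
    # sets mildly enriched) — real cell types differ transcriptome-wide,
    # not only at their defining markers
    type_w = np.tile(base_w, (len(types), 1))
    prog_start = len(marker_genes) + len(MITO_GENES) + params.n_variable_planted
    program_genes: dict[str, list[str]] = {}
    for ti, t in enumerate(types):
        for g in params.markers.get(t, ()):
            type_w[ti, gene_idx[g]] *= params.marker_fold
        lo = prog_start + ti * params.n_program_genes
        hi = min(lo + params.n_program_genes, G)
        type_w[ti, lo:hi] *= params.program_fold
        program_genes[t] = genes[lo:hi]
    mito_w = rng.lognormal(0.0, 0.5, len(MITO_GENES))
    mito_w /= mito_w.sum()
    mito_slice = slice(len(marker_genes), len(marker_genes) + len(MITO_GENES))

    # library sizes and planted QC failures
    sig = np.sqrt(np.log1p(params.lib_size_cv**2))
    lib = params.lib_size_mean * rng.lognormal(-sig**2 / 2.0, sig, size=n)
    n_fail = int(round(params.lowq_fraction * n))
    fail_idx = rng.choice(n, size=n_fail, replace=False)
    planted = np.array(["none"] * n, dtype=object)
    half = n_fail // 2
    planted[fail_idx[:half]] = "low_genes"
    planted[fail_idx[half:]] = "high_mito"
    lib[fail_idx[:half]] *= params.lowq_lib_scale

    a, b = _MITO_BETA
    mito_f = rng.beta(a, b, size=n)
    mito_f[planted == "high_mito"] = params.mito_fraction_high

    # expected counts and NB sampling, per cell block by type
    X = np.zeros((G, n))
    for ti in range(len(types)):
        cells = np.flatnonzero(cell_type == ti)
        if cells.size == 0:
            continue
        w = np.tile(type_w[ti], (cells.size, 1)).T  # G x k
        if hv_genes:
            rows = [gene_idx[g] for g in hv_genes]
            up = hv_half[cells]
            w[np.ix_(rows, np.flatnonzero(up))] *= params.variable_fold
        p_non = w / w.sum(axis=0, keepdims=True)
        mu = p_non * (lib[cells] * (1 - mito_f[cells]))[None, :]
        mu[mito_slice, :] = mito_w[:, None] * (lib[cells] * mito_f[cells])[None, :]
        X[:, cells] = mu
    alpha = params.dispersion
    lam = rng.gamma(1.0 / alpha, alpha * np.clip(X, 1e-12, None))
    # mitochondrial genes stay Poisson: their summed share per cell must
    # track the drawn target closely for planted QC outcomes to be exact
    lam[mito_slice, :] = X[mito_slice, :]
    counts = rng.poisson(lam).astype(np.int32)

    barcodes = [f"CELL{i:05d}" for i in range(n)]
    truth = pd.DataFrame(
        {
            "barcode": barcodes,
            "cell_type": [types[t] for t in cell_type],
            "planted_fail": planted,
            "lib_size": lib,
            "mito_target": mito_f,
        }
    )
    if hv_genes:
        truth.attrs["planted_variable_genes"] = hv_genes
    truth.attrs["program_genes"] = program_genes
    # expected per-gene library shares (before HV perturbation), for
    # moment-based recovery checks: E[count_gc] = share_gt * L_c * (1 - f_c)
    # for non-mito genes and mito_share_g * L_c * f_c for mito genes
    share = pd.DataFrame(
        {t: type_w[ti] / type_w[ti].sum() for ti, t in enumerate(types)},
        index=genes,
    )
    share.iloc[mito_slice] = 0.0
    share /= share.sum(axis=0)
    truth.attrs["nonmito_share"] = share
    truth.attrs["mito_share"] = pd.Series(mito_w, index=list(MITO_GENES))
    truth.attrs["dispersion"] = alpha
    mat = CountMatrix(counts=sparse.csr_matrix(counts), genes=genes, barcodes=barcodes)
    return mat, truth
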