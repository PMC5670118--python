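"""Hierarchical nonnegative sparse coding with max pooling (SHMAX).

The network alternates sparse-coding layers with max-pooling layers,
grouped into "big layers".  Each coding layer carries a dictionary A whose
columns a_i satisfy ||a_i||^2 <= 1; a patch x is encoded by the nonnegative
lasso

    minimize_{s >= 0}  ||x - A s||^2 + lambda ||s||_1,

and the coefficients s are the unit responses (hence nonnegative).  The
lambda parameter trades reconstruction error against population sparseness;
the reference configuration uses 0.15 for the first two big layers and 0.1
above.  Dictionaries are learned layer-wise from randomly sampled patches
by alternating batched coordinate-descent coding with per-column dictionary
updates projected onto the unit ball, which makes the outer objective
monotone non-increasing.

The module also provides the geometry calculators (receptive-field size and
unit count) and the two-path receptive-field control in which two
consecutive big layers are each split into parallel sets with engineered
kernel sizes, so that units in different layers share the same RF size.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Dictionary",
    "LayerSpec",
    "NetworkSpec",
    "TwoPathSplit",
    "ShmaxModel",
    "ShmaxResults",
    "encode",
    "kkt_violation",
    "learn_dictionary",
    "sample_patches",
    "forward",
    "build_two_path",
    "rf_size",
    "unit_count",
    "randomize_weights",
    "desk_spec",
]


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class Dictionary:
    """Unit-ball-constrained basis matrix for one coding layer."""

    bases: np.ndarray                       # (patch_dim, M)
    patch_shape: tuple[int, int, int]       # (height, width, channels)

    def __post_init__(self) -> None:
        self.bases = np.asarray(self.bases, dtype=float)
        d = int(np.prod(self.patch_shape))
        if self.bases.shape[0] != d:
            raise ValueError(
                f"bases rows {self.bases.shape[0]} != patch dim {d}")
        norms2 = (self.bases ** 2).sum(axis=0)
        if (norms2 > 1.0 + 1e-9).any():
            raise ValueError("dictionary column squared norms exceed 1")

    @property
    def n_atoms(self) -> int:
        return self.bases.shape[1]


@dataclass
class LayerSpec:
    kind: str                    # "sparse_coding" | "max_pool"
    kernel: int
    stride: int
    padding: int = 0
    m: int | None = None         # filters (coding layers)
    lam: float | None = None     # sparsity weight (coding layers)

    def __post_init__(self) -> None:
        if self.kind not in ("sparse_coding", "max_pool"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kernel < 1 or self.stride < 1 or self.padding < 0:
            raise ValueError("layer geometry must be positive")
        if self.kind == "sparse_coding":
            if not self.m or self.m < 1:
                raise ValueError("coding layer needs m >= 1 filters")
            if self.lam is None or self.lam <= 0:
                raise ValueError("coding layer needs lambda > 0")


@dataclass
class TwoPathSplit:
    """Descriptor of the two-path receptive-field control.

    The coding layer of big layer ``lower_big`` is split into set b
    (kernel ``k_b``, ``m_b`` filters, padding ``pad_b``) and set c (the
    baseline kernel, ``m_c`` filters); the coding layer of ``upper_big``
    runs as set a on the c path and set d on the b path.  Kernel and
    padding arithmetic guarantees rf(a) == rf(b) > rf(c) and equal map
    sizes on both paths at the merge.
    """

    lower_big: int
    upper_big: int
    m_b: int
    m_c: int
    k_b: int
    pad_b: int


@dataclass
class NetworkSpec:
    """Ordered layers plus the grouping of layers into big layers."""

    layers: list[LayerSpec]
    grouping: list[list[int]]                 # big layer -> layer indices
    split: TwoPathSplit | None = None

    def __post_init__(self) -> None:
        seen = sorted(i for grp in self.grouping for i in grp)
        if seen != list(range(len(self.layers))):
            raise ValueError("grouping must cover every layer exactly once")

    @property
    def n_big(self) -> int:
        return len(self.grouping)

    def coding_layers(self) -> list[int]:
        return [i for i, l in enumerate(self.layers)
                if l.kind == "sparse_coding"]

    def big_of(self, layer: int) -> int:
        for b, grp in enumerate(self.grouping):
            if layer in grp:
                return b
        raise ValueError(f"layer {layer} not in grouping")

    def to_json(self) -> dict:
        return {
            "layers": [vars(l) for l in self.layers],
            "grouping": self.grouping,
            "split": vars(self.split) if self.split else None,
        }

    @classmethod
    def from_json(cls, doc: dict) -> "NetworkSpec":
        layers = [LayerSpec(**l) for l in doc["layers"]]
        split = TwoPathSplit(**doc["split"]) if doc.get("split") else None
        return cls(layers=layers, grouping=[list(g) for g in doc["grouping"]],
                   split=split)


def desk_spec(n_big: int = 3, m: tuple[int, ...] = (32, 48, 64),
              lam: tuple[float, ...] | None = None,
              kernels: tuple[int, ...] = (7, 5, 3),
              strides: tuple[int, ...] = (2, 1, 1),
              pool_last: bool = False) -> NetworkSpec:
    """Desk-scale default: per big layer, a coding layer plus 2x2/2 max pool.

    The reference lambda schedule (0.15 for the first two big layers, 0.1
    above) is applied unless an explicit schedule is given.  The final big
    layer is coding-only by default (its maps are already small at desk
    image sizes, and the big layer's response is its final maps either way).
    """
    if lam is None:
        lam = tuple(0.15 if b < 2 else 0.1 for b in range(n_big))
    layers, grouping = [], []
    for b in range(n_big):
        i = len(layers)
        layers.append(LayerSpec("sparse_coding", kernel=kernels[b],
                                stride=strides[b], m=m[b], lam=lam[b]))
        if b < n_big - 1 or pool_last:
            layers.append(LayerSpec("max_pool", kernel=2, stride=2))
            grouping.append([i, i + 1])
        else:
            grouping.append([i])
    return NetworkSpec(layers=layers, grouping=grouping)


# ---------------------------------------------------------------------------
# Nonnegative lasso coding
# ---------------------------------------------------------------------------

def encode(x: np.ndarray, dictionary: Dictionary | np.ndarray, lam: float,
           max_iter: int = 1000, tol: float = 1e-10,
           kkt_tol: float | None = 1e-8,
           s0: np.ndarray | None = None) -> np.ndarray:
    """Solve the nonnegative lasso by cyclic coordinate descent.

    ``x`` may be a single patch vector (returns an M-vector) or a
    (patch_dim, N) batch (returns (M, N)); every patch is an independent
    problem, so one coordinate sweep updates that coordinate for all
    patches at once.  A sweep whose largest coefficient change falls below
    ``tol`` triggers a stationarity check; iteration stops once the KKT
    violation is below ``kkt_tol`` (overcomplete dictionaries can make the
    coefficient change tiny long before stationarity).  ``s0`` warm-starts
    the iteration (coordinate descent never increases the objective, so a
    warm start can only improve on its initializer).
    """
    A = dictionary.bases if isinstance(dictionary, Dictionary) else np.asarray(dictionary)
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = x[:, None] if single else x
    if not np.isfinite(X).all():
        raise ValueError("non-finite input to encode")
    if X.shape[0] != A.shape[0]:
        raise ValueError(f"patch dim {X.shape[0]} != dictionary dim {A.shape[0]}")
    M = A.shape[1]
    G = A.T @ A
    B = A.T @ X
    diag = np.diag(G).copy()
    active = diag > 1e-12
    S = np.zeros((M, X.shape[1])) if s0 is None else np.array(s0, dtype=float)
    half_lam = lam / 2.0
    for _ in range(max_iter):
        delta = 0.0
        for m in range(M):
            if not active[m]:
                continue
            # residual correlation with atom m, excluding its own term
            r = B[m] - G[m] @ S + diag[m] * S[m]
            new = np.maximum(0.0, (r - half_lam) / diag[m])
            d = np.abs(new - S[m]).max()
            if d > delta:
                delta = d
            S[m] = new
        if delta < tol:
            if kkt_tol is None:
                break
            g = 2.0 * (G @ S - B) + lam
            viol = np.maximum(np.where(S > 0, np.abs(g), 0.0),
                              np.where(S > 0, 0.0, -g)).max()
            if viol < kkt_tol:
                break
    return S[:, 0] if single else S


def kkt_violation(x: np.ndarray, dictionary: Dictionary | np.ndarray,
                  s: np.ndarray, lam: float) -> float:
    """Max violation of the nonnegative-lasso stationarity conditions.

    With g = 2 A^T (A s - x) + lambda: g_i = 0 where s_i > 0 and g_i >= 0
    where s_i = 0.  Returns the largest absolute violation.
    """
    A = dictionary.bases if isinstance(dictionary, Dictionary) else np.asarray(dictionary)
    X = x[:, None] if x.ndim == 1 else x
    S = s[:, None] if s.ndim == 1 else s
    g = 2.0 * A.T @ (A @ S - X) + lam
    active = S > 0
    v1 = np.abs(g[active]).max() if active.any() else 0.0
    v2 = np.maximum(0.0, -g[~active]).max() if (~active).any() else 0.0
    return float(max(v1, v2))


def _objective(X: np.ndarray, A: np.ndarray, S: np.ndarray, lam: float) -> float:
    R = X - A @ S
    return float((R ** 2).sum() + lam * S.sum())


def learn_dictionary(patches: np.ndarray, m: int, lam: float,
                     n_iters: int = 20, seed: int = 0,
                     patch_shape: tuple[int, int, int] | None = None,
                     tol: float = 1e-6,
                     coding_kwargs: dict | None = None
                     ) -> tuple[Dictionary, dict]:
    """Alternating sparse coding / dictionary update on a patch batch.

    ``patches`` is (n_patches, patch_dim).  The dictionary update is block
    coordinate descent over columns: each column's quadratic subproblem has
    a Hessian proportional to the identity, so projecting its unconstrained
    minimizer onto the unit ball is the exact constrained minimizer and the
    total objective never increases.  Columns never used by the codes are
    left untouched.  Stops early when the relative objective change drops
    below ``tol``.
    """
    if n_iters < 1:
        raise ValueError("n_iters must be >= 1")
    P = np.asarray(patches, dtype=float)
    n, d = P.shape
    if n < m:
        import warnings
        warnings.warn(f"only {n} patches for {m} atoms", stacklevel=2)
    rng = np.random.default_rng(seed)
    # init: random patches rescaled to unit norm (the constraint boundary,
    # where optimal atoms generically sit; small-norm atoms never clear the
    # soft threshold and would stay dead)
    idx = rng.choice(n, size=m, replace=n < m)
    A = P[idx].T.astype(float).copy()
    A += 1e-6 * rng.standard_normal(A.shape)   # break exact duplicates
    A /= np.maximum(np.linalg.norm(A, axis=0), 1e-12)
    X = P.T
    ck = coding_kwargs or {}
    objective_trace = []
    S = None
    for _ in range(n_iters):
        S = encode(X, A, lam, s0=S, **ck)
        SST = S @ S.T
        XST = X @ S.T
        diag = np.diag(SST)
        for j in range(m):
            if diag[j] <= 1e-12:
                continue
            a = (XST[:, j] - A @ SST[:, j] + A[:, j] * diag[j]) / diag[j]
            norm = np.linalg.norm(a)
            if norm > 1.0:
                a /= norm
            A[:, j] = a
        obj = _objective(X, A, S, lam)
        objective_trace.append(obj)
        if len(objective_trace) > 1:
            prev = objective_trace[-2]
            if prev > 0 and (prev - obj) / prev < tol:
                break
    shape = patch_shape or (d, 1, 1)
    info = {"objective": objective_trace, "seed": seed, "lam": lam}
    return Dictionary(bases=A, patch_shape=shape), info


# ---------------------------------------------------------------------------
# Patch sampling and the forward pass
# ---------------------------------------------------------------------------

def sample_patches(maps: list[np.ndarray], patch_size: int,
                   n_per_image: int = 200, seed: int = 0) -> np.ndarray:
    """Uniformly sample patches from feature maps (H x W x C arrays).

    Returns (n_images * n_per_image, patch_size**2 * C); the channel count
    must agree across images.
    """
    rng = np.random.default_rng(seed)
    out = []
    for fm in maps:
        fm = np.atleast_3d(fm)
        h, w, _ = fm.shape
        if patch_size > h or patch_size > w:
            raise ValueError(
                f"patch {patch_size} larger than map {h}x{w}")
        for _ in range(n_per_image):
            y = rng.integers(0, h - patch_size + 1)
            x = rng.integers(0, w - patch_size + 1)
            out.append(fm[y:y + patch_size, x:x + patch_size, :].ravel())
    if not out:
        return np.zeros((0, patch_size * patch_size))
    return np.asarray(out)


def _im2col(fm: np.ndarray, kernel: int, stride: int, padding: int
            ) -> tuple[np.ndarray, int, int]:
    """(patch_dim, n_patches) column matrix plus the output grid shape."""
    fm = np.atleast_3d(fm)
    if padding:
        fm = np.pad(fm, ((padding, padding), (padding, padding), (0, 0)))
    h, w, c = fm.shape
    if kernel > h or kernel > w:
        raise ValueError(f"kernel {kernel} exceeds padded map {h}x{w}")
    win = sliding_window_view(fm, (kernel, kernel, c))[::stride, ::stride, 0]
    oh, ow = win.shape[:2]
    cols = win.reshape(oh * ow, -1).T
    return cols, oh, ow


def _max_pool(fm: np.ndarray, kernel: int, stride: int) -> np.ndarray:
    fm = np.atleast_3d(fm)
    h, w, c = fm.shape
    if kernel > h or kernel > w:
        raise ValueError(f"pool kernel {kernel} exceeds map {h}x{w}")
    win = sliding_window_view(fm, (kernel, kernel), axis=(0, 1))
    win = win[::stride, ::stride]
    return win.max(axis=(-2, -1))


def _run_chain(layers: list[LayerSpec], dicts: dict[int, Dictionary],
               fm: np.ndarray, layer_offset: int = 0,
               coding_kwargs: dict | None = None) -> list[np.ndarray]:
    outputs = []
    ck = coding_kwargs or {}
    for i, layer in enumerate(layers):
        gi = layer_offset + i
        if layer.kind == "sparse_coding":
            if gi not in dicts:
                raise ValueError(f"no dictionary for coding layer {gi}")
            D = dicts[gi]
            cols, oh, ow = _im2col(fm, layer.kernel, layer.stride,
                                   layer.padding)
            if cols.shape[0] != D.bases.shape[0]:
                raise ValueError(
                    f"layer {gi}: patch dim {cols.shape[0]} does not match "
                    f"dictionary dim {D.bases.shape[0]}")
            S = encode(cols, D, layer.lam, **ck)
            fm = S.T.reshape(oh, ow, D.n_atoms)
        else:
            fm = _max_pool(fm, layer.kernel, layer.stride)
        outputs.append(fm)
    return outputs


def _run_chain_batch(layers: list[LayerSpec], dicts: dict,
                     fms: list[np.ndarray], layer_offset: int = 0,
                     coding_kwargs: dict | None = None
                     ) -> list[list[np.ndarray]]:
    """Run a layer chain over a batch of inputs, encoding all patches of a
    coding layer in one nonnegative-lasso call (much better vectorization
    than per-image forward passes).  Returns per-layer lists of maps."""
    ck = coding_kwargs or {}
    outputs: list[list[np.ndarray]] = []
    for i, layer in enumerate(layers):
        gi = layer_offset + i
        if layer.kind == "sparse_coding":
            if gi not in dicts:
                raise ValueError(f"no dictionary for coding layer {gi}")
            D = dicts[gi]
            cols_list, grids = [], []
            for fm in fms:
                cols, oh, ow = _im2col(fm, layer.kernel, layer.stride,
                                       layer.padding)
                cols_list.append(cols)
                grids.append((oh, ow))
            allcols = np.hstack(cols_list)
            if allcols.shape[0] != D.bases.shape[0]:
                raise ValueError(
                    f"layer {gi}: patch dim {allcols.shape[0]} does not "
                    f"match dictionary dim {D.bases.shape[0]}")
            S = encode(allcols, D, layer.lam, **ck)
            fms_new, pos = [], 0
            for (oh, ow) in grids:
                n = oh * ow
                fms_new.append(S[:, pos:pos + n].T.reshape(oh, ow,
                                                           D.n_atoms))
                pos += n
            fms = fms_new
        else:
            fms = [_max_pool(fm, layer.kernel, layer.stride) for fm in fms]
        outputs.append(fms)
    return outputs


def forward_batch(net: NetworkSpec, dictionaries: dict,
                  images, coding_kwargs: dict | None = None) -> dict:
    """Batched forward pass over a list of images.

    Returns ``{"big": [per-big-layer list of per-image maps]}`` and, for
    two-path specs, ``"sets"`` with per-set lists of per-image maps.
    """
    fms = [np.atleast_3d(np.asarray(getattr(im, "pixels", im), dtype=float))
           for im in images]
    if net.split is None:
        outputs = _run_chain_batch(net.layers, dictionaries, fms,
                                   coding_kwargs=coding_kwargs)
        big = [outputs[grp[-1]] for grp in net.grouping]
        return {"big": big}
    sp = net.split
    pre = [i for grp in net.grouping[:sp.lower_big] for i in grp]
    outs = _run_chain_batch([net.layers[i] for i in pre], dictionaries, fms,
                            coding_kwargs=coding_kwargs)
    fms_in = outs[-1] if outs else fms
    lower_grp = net.grouping[sp.lower_big]
    upper_grp = net.grouping[sp.upper_big]
    lower_code = net.layers[lower_grp[0]]
    lower_rest = [net.layers[i] for i in lower_grp[1:]]
    spec_c = replace(lower_code, m=sp.m_c)
    spec_b = replace(lower_code, m=sp.m_b, kernel=sp.k_b, padding=sp.pad_b)
    out_c = _run_chain_batch([spec_c] + lower_rest,
                             {0: dictionaries[("c", 0)]}, fms_in,
                             coding_kwargs=coding_kwargs)
    out_b = _run_chain_batch([spec_b] + lower_rest,
                             {0: dictionaries[("b", 0)]}, fms_in,
                             coding_kwargs=coding_kwargs)
    upper_code = net.layers[upper_grp[0]]
    upper_rest = [net.layers[i] for i in upper_grp[1:]]
    out_a = _run_chain_batch([upper_code] + upper_rest,
                             {0: dictionaries[("a", 0)]}, out_c[-1],
                             coding_kwargs=coding_kwargs)
    out_d = _run_chain_batch([upper_code] + upper_rest,
                             {0: dictionaries[("d", 0)]}, out_b[-1],
                             coding_kwargs=coding_kwargs)
    big = [outs[grp[-1]] for grp in net.grouping[:sp.lower_big]]
    big += [out_c[-1],
            [np.concatenate([a, d], axis=2)
             for a, d in zip(out_a[-1], out_d[-1])]]
    return {"big": big,
            "sets": {"a": out_a[-1], "b": out_b[-1], "c": out_c[-1],
                     "d": out_d[-1]}}


def forward(net: NetworkSpec, dictionaries: dict[int, Dictionary],
            img_or_pixels, coding_kwargs: dict | None = None) -> dict:
    """Run the network; returns per-layer maps and per-big-layer outputs.

    For a two-path spec the result also carries the set outputs under
    ``"sets"`` with keys ``"a"``, ``"b"``, ``"c"`` (final maps of each set's
    big layer).
    """
    pixels = getattr(img_or_pixels, "pixels", img_or_pixels)
    fm = np.atleast_3d(np.asarray(pixels, dtype=float))
    if net.split is None:
        outputs = _run_chain(net.layers, dictionaries, fm,
                             coding_kwargs=coding_kwargs)
        big = [outputs[grp[-1]] for grp in net.grouping]
        return {"layers": outputs, "big": big}
    return _forward_two_path(net, dictionaries, fm, coding_kwargs)


def _forward_two_path(net, dicts, fm, coding_kwargs):
    sp = net.split
    lower_grp = net.grouping[sp.lower_big]
    upper_grp = net.grouping[sp.upper_big]
    pre = [i for grp in net.grouping[:sp.lower_big] for i in grp]
    outputs = _run_chain([net.layers[i] for i in pre], dicts, fm,
                         coding_kwargs=coding_kwargs)
    fm_in = outputs[-1] if outputs else fm

    lower_code = net.layers[lower_grp[0]]
    lower_rest = [net.layers[i] for i in lower_grp[1:]]
    # path c: baseline kernel; path b: enlarged kernel with padding
    spec_c = replace(lower_code, m=sp.m_c)
    spec_b = replace(lower_code, m=sp.m_b, kernel=sp.k_b, padding=sp.pad_b)
    out_c = _run_chain([spec_c] + lower_rest,
                       {0: dicts[("c", 0)]}, fm_in, coding_kwargs=coding_kwargs)
    out_b = _run_chain([spec_b] + lower_rest,
                       {0: dicts[("b", 0)]}, fm_in, coding_kwargs=coding_kwargs)
    set_c, set_b = out_c[-1], out_b[-1]

    upper_code = net.layers[upper_grp[0]]
    upper_rest = [net.layers[i] for i in upper_grp[1:]]
    out_a = _run_chain([upper_code] + upper_rest, {0: dicts[("a", 0)]},
                       set_c, coding_kwargs=coding_kwargs)
    out_d = _run_chain([upper_code] + upper_rest, {0: dicts[("d", 0)]},
                       set_b, coding_kwargs=coding_kwargs)
    set_a, set_d = out_a[-1], out_d[-1]
    if set_a.shape[:2] != set_d.shape[:2]:
        raise AssertionError(
            f"two-path merge size mismatch: {set_a.shape} vs {set_d.shape}")
    merged = np.concatenate([set_a, set_d], axis=2)
    return {"layers": outputs + out_c + out_a,
            "big": [outputs[grp[-1]] for grp in net.grouping[:sp.lower_big]]
                   + [set_c, merged],
            "sets": {"a": set_a, "b": set_b, "c": set_c, "d": set_d}}


# ---------------------------------------------------------------------------
# Geometry calculators
# ---------------------------------------------------------------------------

def rf_size(net: NetworkSpec, layer: int) -> int:
    """Receptive-field side length of units in ``layer`` (0-based), in pixels.

    Standard recursion: rf_l = rf_{l-1} + (k_l - 1) * prod(strides below l).
    """
    if not 0 <= layer < len(net.layers):
        raise ValueError(f"layer {layer} out of range")
    rf, jump = 1, 1
    for l in net.layers[:layer + 1]:
        rf += (l.kernel - 1) * jump
        jump *= l.stride
    return rf


def _out_size(size: int, l: LayerSpec) -> int:
    out = (size + 2 * l.padding - l.kernel) // l.stride + 1
    if out < 1:
        raise ValueError(
            f"infeasible geometry: input {size}, kernel {l.kernel}, "
            f"stride {l.stride}, padding {l.padding} -> output {out}")
    return out


def unit_count(net: NetworkSpec, layer: int, input_size: int) -> int:
    """Units (height x width x filters) in the maps of ``layer``."""
    if not 0 <= layer < len(net.layers):
        raise ValueError(f"layer {layer} out of range")
    size = input_size
    channels = 1
    for l in net.layers[:layer + 1]:
        size = _out_size(size, l)
        if l.kind == "sparse_coding":
            channels = l.m
    return size * size * channels


def build_two_path(net: NetworkSpec, lower_big: int, upper_big: int,
                   split: float = 0.5) -> NetworkSpec:
    """Construct the two-path receptive-field control from a baseline spec.

    The lower big layer's filters are partitioned into set b (fraction
    ``split``) and set c; set c keeps the baseline kernel while set b's
    kernel is enlarged so that after the upper big layer's coding (set a,
    on the c path) the RF of set a equals that of set b exactly:

        k_b = k_c + (rf gain of the upper big layer) / (jump below lower).

    Padding on the b path keeps both paths' map sizes equal at the merge.
    """
    if upper_big != lower_big + 1:
        raise ValueError("lower and upper big layers must be consecutive")
    if not 0 <= lower_big < net.n_big - 1:
        raise ValueError(f"big layer {lower_big} out of range")
    if net.split is not None:
        raise ValueError("spec already carries a two-path split")

    lower_grp = net.grouping[lower_big]
    upper_grp = net.grouping[upper_big]
    lower_code = net.layers[lower_grp[0]]
    if lower_code.kind != "sparse_coding":
        raise ValueError("lower big layer must start with a coding layer")

    # jump (stride product) below the lower big layer
    jump = 1
    for grp in net.grouping[:lower_big]:
        for i in grp:
            jump *= net.layers[i].stride
    # stride product inside the lower big layer
    jump_lower = 1
    for i in lower_grp:
        jump_lower *= net.layers[i].stride
    # rf gain contributed by the upper big layer, in lower-input jumps
    gain = 0
    j = jump * jump_lower
    for i in upper_grp:
        gain += (net.layers[i].kernel - 1) * j
        j *= net.layers[i].stride
    if gain % jump:
        raise ValueError(
            f"infeasible split: upper-layer rf gain {gain} is not a "
            f"multiple of the lower-input jump {jump}")
    k_b = lower_code.kernel + gain // jump
    extra = k_b - lower_code.kernel
    if extra % 2:
        raise ValueError(
            f"infeasible split: kernel enlargement {extra} "
            f"(k_b={k_b}, k_c={lower_code.kernel}) is odd, so no symmetric "
            f"padding can equalize the map sizes")
    pad_b = extra // 2
    m_b = max(1, int(round(lower_code.m * split)))
    m_c = lower_code.m - m_b
    if m_c < 1:
        raise ValueError("split leaves no filters in set c")
    out = copy.deepcopy(net)
    out.split = TwoPathSplit(lower_big=lower_big, upper_big=upper_big,
                             m_b=m_b, m_c=m_c, k_b=k_b, pad_b=pad_b)
    return out


def rf_size_sets(net: NetworkSpec) -> dict[str, int]:
    """RF sizes of the two-path sets a, b, c (final maps of their big layers)."""
    sp = net.split
    if sp is None:
        raise ValueError("spec has no two-path split")
    jump = 1
    rf = 1
    for grp in net.grouping[:sp.lower_big]:
        for i in grp:
            l = net.layers[i]
            rf += (l.kernel - 1) * jump
            jump *= l.stride
    lower_grp = net.grouping[sp.lower_big]
    upper_grp = net.grouping[sp.upper_big]

    def chain_rf(rf0, jump0, kernels_strides):
        r, j = rf0, jump0
        for k, s in kernels_strides:
            r += (k - 1) * j
            j *= s
        return r, j

    lower_rest = [(net.layers[i].kernel, net.layers[i].stride)
                  for i in lower_grp[1:]]
    lc = net.layers[lower_grp[0]]
    rf_c, j_c = chain_rf(rf, jump, [(lc.kernel, lc.stride)] + lower_rest)
    rf_b, _ = chain_rf(rf, jump, [(sp.k_b, lc.stride)] + lower_rest)
    upper = [(net.layers[i].kernel, net.layers[i].stride) for i in upper_grp]
    rf_a, _ = chain_rf(rf_c, j_c, upper)
    return {"a": rf_a, "b": rf_b, "c": rf_c}


# ---------------------------------------------------------------------------
# Random-weight control
# ---------------------------------------------------------------------------

def randomize_weights(dictionaries: dict, seed: int = 0) -> dict:
    """Replace every basis column with an i.i.d. Gaussian unit-norm vector."""
    rng = np.random.default_rng(seed)
    out = {}
    for key, D in dictionaries.items():
        A = rng.standard_normal(D.bases.shape)
        A /= np.linalg.norm(A, axis=0)
        out[key] = Dictionary(bases=A, patch_shape=D.patch_shape)
    return out


# ---------------------------------------------------------------------------
# Model / Results surface
# ---------------------------------------------------------------------------

class ShmaxModel:
    """Layer-wise trainable SHMAX network.

    Parameters
    ----------
    spec : NetworkSpec
        Architecture (layers, kernels, strides, lambdas, grouping, and the
        optional two-path split).
    n_patches_per_image : int
        Patches sampled per training image per coding layer (the reference
        procedure uses 200).
    n_iters : int
        Outer alternations of the dictionary learner per layer.
    """

    def __init__(self, spec: NetworkSpec, n_patches_per_image: int = 200,
                 n_iters: int = 15, coding_kwargs: dict | None = None):
        self.spec = spec
        self.n_patches_per_image = n_patches_per_image
        self.n_iters = n_iters
        self.coding_kwargs = coding_kwargs or {"max_iter": 100, "tol": 1e-7,
                                               "kkt_tol": None}

    def fit(self, images: list, seed: int = 0) -> "ShmaxResults":
        """Train dictionaries layer by layer on the given training images."""
        if not images:
            raise ValueError("no training images")
        if self.spec.split is None:
            dicts, info = self._fit_chain(images, seed)
        else:
            dicts, info = self._fit_two_path(images, seed)
        return ShmaxResults(self, dicts, info)

    # -- plain chain --------------------------------------------------------

    def _fit_chain(self, images, seed):
        pixels = [np.atleast_3d(np.asarray(getattr(im, "pixels", im),
                                           dtype=float)) for im in images]
        rng_root = np.random.SeedSequence(seed)
        dicts: dict = {}
        info: dict = {"layers": {}, "seed": seed}
        maps = pixels
        for i, layer in enumerate(self.spec.layers):
            if layer.kind == "sparse_coding":
                sub_seed = int(rng_root.spawn(1)[0].generate_state(1)[0]
                               % (2 ** 31))
                c = maps[0].shape[2]
                P = sample_patches(maps, layer.kernel,
                                   self.n_patches_per_image, seed=sub_seed)
                D, li = learn_dictionary(
                    P, layer.m, layer.lam, n_iters=self.n_iters,
                    seed=sub_seed, patch_shape=(layer.kernel, layer.kernel, c),
                    coding_kwargs=self.coding_kwargs)
                dicts[i] = D
                info["layers"][i] = li
                maps = [self._apply_coding(fm, layer, D) for fm in maps]
            else:
                maps = [_max_pool(fm, layer.kernel, layer.stride)
                        for fm in maps]
        return dicts, info

    def _apply_coding(self, fm, layer, D):
        cols, oh, ow = _im2col(fm, layer.kernel, layer.stride, layer.padding)
        S = encode(cols, D, layer.lam, **self.coding_kwargs)
        return S.T.reshape(oh, ow, D.n_atoms)

    # -- two-path -----------------------------------------------------------

    def _fit_two_path(self, images, seed):
        sp = self.spec.split
        pixels = [np.atleast_3d(np.asarray(getattr(im, "pixels", im),
                                           dtype=float)) for im in images]
        rng_root = np.random.SeedSequence(seed)

        def next_seed():
            return int(rng_root.spawn(1)[0].generate_state(1)[0] % (2 ** 31))

        dicts: dict = {}
        info: dict = {"layers": {}, "seed": seed}
        maps = pixels
        # shared prefix
        for b in range(sp.lower_big):
            for i in self.spec.grouping[b]:
                layer = self.spec.layers[i]
                if layer.kind == "sparse_coding":
                    c = maps[0].shape[2]
                    P = sample_patches(maps, layer.kernel,
                                       self.n_patches_per_image,
                                       seed=next_seed())
                    D, li = learn_dictionary(
                        P, layer.m, layer.lam, n_iters=self.n_iters,
                        seed=next_seed(),
                        patch_shape=(layer.kernel, layer.kernel, c),
                        coding_kwargs=self.coding_kwargs)
                    dicts[i] = D
                    info["layers"][i] = li
                    maps = [self._apply_coding(fm, layer, D) for fm in maps]
                else:
                    maps = [_max_pool(fm, layer.kernel, layer.stride)
                            for fm in maps]
        # split big layer
        lower_grp = self.spec.grouping[sp.lower_big]
        lower_code = self.spec.layers[lower_grp[0]]
        lower_rest = [self.spec.layers[i] for i in lower_grp[1:]]
        c_in = maps[0].shape[2]
        branches = {
            "c": replace(lower_code, m=sp.m_c),
            "b": replace(lower_code, m=sp.m_b, kernel=sp.k_b,
                         padding=sp.pad_b),
        }
        branch_maps = {}
        for name, bl in branches.items():
            P = sample_patches(maps, bl.kernel, self.n_patches_per_image,
                               seed=next_seed())
            D, li = learn_dictionary(
                P, bl.m, bl.lam, n_iters=self.n_iters, seed=next_seed(),
                patch_shape=(bl.kernel, bl.kernel, c_in),
                coding_kwargs=self.coding_kwargs)
            dicts[(name, 0)] = D
            info["layers"][f"{name}0"] = li
            bm = [self._apply_coding(fm, bl, D) for fm in maps]
            for l in lower_rest:
                bm = [_max_pool(fm, l.kernel, l.stride) for fm in bm]
            branch_maps[name] = bm
        # upper big layer: set a on path c, set d on path b
        upper_grp = self.spec.grouping[sp.upper_big]
        upper_code = self.spec.layers[upper_grp[0]]
        for name, src in (("a", "c"), ("d", "b")):
            src_maps = branch_maps[src]
            c_in2 = src_maps[0].shape[2]
            P = sample_patches(src_maps, upper_code.kernel,
                               self.n_patches_per_image, seed=next_seed())
            D, li = learn_dictionary(
                P, upper_code.m, upper_code.lam, n_iters=self.n_iters,
                seed=next_seed(),
                patch_shape=(upper_code.kernel, upper_code.kernel, c_in2),
                coding_kwargs=self.coding_kwargs)
            dicts[(name, 0)] = D
            info["layers"][f"{name}0"] = li
        return dicts, info


class ShmaxResults:
    """A trained SHMAX: dictionaries plus training diagnostics."""

    def __init__(self, model: ShmaxModel, dictionaries: dict, info: dict):
        self.model = model
        self.spec = model.spec
        self.dictionaries = dictionaries
        self.info = info

    def forward(self, img) -> dict:
        return forward(self.spec, self.dictionaries, img,
                       coding_kwargs=self.model.coding_kwargs)

    def forward_batch(self, images) -> dict:
        return forward_batch(self.spec, self.dictionaries, images,
                             coding_kwargs=self.model.coding_kwargs)

    def objective_traces(self) -> dict:
        return {k: v["objective"] for k, v in self.info["layers"].items()}

    def with_random_weights(self, seed: int = 0) -> "ShmaxResults":
        return ShmaxResults(self.model,
                            randomize_weights(self.dictionaries, seed),
                            {"layers": {}, "seed": seed, "random": True})
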