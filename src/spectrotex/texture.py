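"""Census-transform texture descriptors for spectrogram images.

Three pixel-level operators code each interior pixel of a grayscale image
against its 8-neighborhood (radius 1):

* **Census transform (CT)** — bit 1 where center >= neighbor, giving an
  8-bit code per pixel.
* **Completed local binary patterns (CLBP)** — the neighbor differences
  d_p = g_p - g_c are split into a sign part s_p (bit 1 where d_p >= 0,
  the S code), a magnitude part m_p = |d_p| thresholded at the image mean
  magnitude (the M code), and a center code C = [g_c >= image gray mean].
  S and M codes are optionally collapsed to the 10-symbol
  rotation-invariant uniform (riu2) alphabet.
* **Local ternary patterns (LTP)** — a three-valued comparison with dead
  zone +-mu (q = +1 iff d_p >= mu, -1 iff d_p <= -mu, else 0), split into
  an "upper" binary code (q == +1) and a "lower" code (q == -1).

Bit order is frozen for reproducibility: the 8 neighbors are scanned
row-major from the top-left, first neighbor -> most significant bit.  The
1-pixel border is excluded from the code maps; a coded pixel belongs to a
spatial-pyramid block according to its own (center) image coordinate.

Descriptors are per-block histograms over a spatial pyramid (levels 0-2:
1 + 4 + 16 = 21 blocks), concatenated level-ascending / row-major:

* **cCENTRIST** — per block, the joint 3-D histogram of (S, M, C) codes:
  10 x 10 x 2 = 200 bins with riu2 (4200 values for 21 blocks).
* **tCENTRIST** — per block, the 256-bin histogram of upper LTP codes
  followed by the 256-bin histogram of lower codes (10752 values).

Histograms are L1-normalized per block by default (blocks can differ in
coded-pixel count at image borders).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .spectrogram import SpectrogramImage

#: 8-neighborhood offsets, row-major from the top-left; offset k maps to
#: bit (7 - k) of every 8-bit code.
NEIGHBOR_OFFSETS = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1),           (0, 1),
    (1, -1), (1, 0), (1, 1),
)


def _riu2_table(p: int = 8) -> np.ndarray:
    """Map raw p-bit codes to the rotation-invariant uniform alphabet.

    Uniform codes (at most 2 circular 0/1 transitions) map to their bit
    count (0..p); all others map to p + 1.
    """
    table = np.empty(2 ** p, dtype=np.int64)
    for code in range(2 ** p):
        bits = [(code >> i) & 1 for i in range(p)]
        transitions = sum(bits[i] != bits[(i + 1) % p] for i in range(p))
        table[code] = sum(bits) if transitions <= 2 else p + 1
    return table


RIU2_TABLE = _riu2_table(8)


@dataclass
class CodeMap:
    """Per-pixel pattern codes for the interior of an image."""

    codes: np.ndarray  # (H - 2R, W - 2R) integer codes
    kind: str          # ct | clbp_s | clbp_m | clbp_c | ltp_upper | ltp_lower
    n_codes: int
    radius: int = 1


def _as_array(img) -> np.ndarray:
    a = img.pixels if isinstance(img, SpectrogramImage) else np.asarray(img)
    if a.ndim != 2:
        raise ValidationError("texture operators expect a 2-D grayscale image")
    if a.shape[0] < 3 or a.shape[1] < 3:
        raise ValidationError(f"image {a.shape} smaller than 3x3")
    return a.astype(np.float64)


def _neighbor_diffs(a: np.ndarray) -> np.ndarray:
    """Stack of g_p - g_c for the 8 offsets, shape (8, H-2, W-2)."""
    h, w = a.shape
    c = a[1:-1, 1:-1]
    return np.stack([a[1 + di:h - 1 + di, 1 + dj:w - 1 + dj] - c
                     for di, dj in NEIGHBOR_OFFSETS])


def _pack_bits(bits: np.ndarray) -> np.ndarray:
    """Pack a (8, H, W) boolean stack into 8-bit codes, MSB = first offset."""
    codes = np.zeros(bits.shape[1:], dtype=np.int64)
    for k in range(8):
        codes |= bits[k].astype(np.int64) << (7 - k)
    return codes


def census_transform(img) -> CodeMap:
    """8-bit census code per interior pixel (bit 1 where center >= neighbor)."""
    a = _as_array(img)
    codes = _pack_bits(_neighbor_diffs(a) <= 0)  # d = g_p - g_c <= 0 <=> g_c >= g_p
    return CodeMap(codes, "ct", 256)


def clbp_codes(img, P: int = 8, R: int = 1, riu2: bool = True,
               m_threshold: str = "magnitude_mean") -> tuple[CodeMap, CodeMap, CodeMap]:
    """Sign, magnitude and center CLBP code maps.

    ``m_threshold`` selects the threshold c of the magnitude code: the mean
    of all magnitudes |d_p| over the image (``"magnitude_mean"``, the CLBP
    convention and default) or the mean gray value (``"gray_mean"``).  The
    center code always thresholds g_c at the mean gray value of the whole
    image.  With ``riu2``, S and M codes live in {0..9}.
    """
    if P != 8 or R != 1:
        raise ValidationError("only P=8, R=1 neighborhoods are supported")
    a = _as_array(img)
    d = _neighbor_diffs(a)
    m = np.abs(d)
    s_codes = _pack_bits(d >= 0)
    c_m = m.mean() if m_threshold == "magnitude_mean" else a.mean()
    m_codes = _pack_bits(m >= c_m)
    c_codes = (a[1:-1, 1:-1] >= a.mean()).astype(np.int64)
    if riu2:
        s_codes = RIU2_TABLE[s_codes]
        m_codes = RIU2_TABLE[m_codes]
        n = 10
    else:
        n = 256
    return (CodeMap(s_codes, "clbp_s", n), CodeMap(m_codes, "clbp_m", n),
            CodeMap(c_codes, "clbp_c", 2))


def ltp_codes(img, mu: float = 5.0, P: int = 8, R: int = 1
              ) -> tuple[CodeMap, CodeMap]:
    """Upper and lower LTP code maps with dead zone +-mu."""
    if P != 8 or R != 1:
        raise ValidationError("only P=8, R=1 neighborhoods are supported")
    if mu <= 0:
        raise ValidationError(f"mu must be > 0, got {mu}")
    d = _neighbor_diffs(_as_array(img))
    upper = _pack_bits(d >= mu)
    lower = _pack_bits(d <= -mu)
    return CodeMap(upper, "ltp_upper", 256), CodeMap(lower, "ltp_lower", 256)


@dataclass(frozen=True)
class Block:
    """A rectangular pixel region [r0, r1) x [c0, c1) in image coordinates."""

    level: int
    r0: int
    r1: int
    c0: int
    c1: int


@dataclass
class PyramidLayout:
    """Spatial-pyramid partition of an H x W image."""

    height: int
    width: int
    levels: tuple[int, ...]
    blocks: list[Block] = field(default_factory=list)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)


def pyramid_blocks(height: int, width: int,
                   levels=(0, 1, 2)) -> PyramidLayout:
    """Partition an image into a 2^L x 2^L grid per level L.

    Blocks at each level tile the image exactly; when a side is not
    divisible the last row/column block absorbs the remainder.  Blocks are
    listed level-ascending, row-major.  Default levels (0, 1, 2) give
    1 + 4 + 16 = 21 blocks.
    """
    levels = tuple(levels)
    if not levels:
        raise ValidationError("levels must be nonempty")
    blocks: list[Block] = []
    for lv in sorted(levels):
        g = 2 ** lv
        if height < g or width < g:
            raise ValidationError(
                f"image {height}x{width} too small for pyramid level {lv}"
            )
        bh, bw = height // g, width // g
        for i in range(g):
            r0, r1 = i * bh, (i + 1) * bh if i < g - 1 else height
            for j in range(g):
                c0, c1 = j * bw, (j + 1) * bw if j < g - 1 else width
                blocks.append(Block(lv, r0, r1, c0, c1))
    return PyramidLayout(height, width, levels, blocks)


@dataclass
class TextureDescriptor:
    """Concatenated per-block histogram feature vector for one image."""

    values: np.ndarray
    extractor: str  # "ccentrist" | "tcentrist"
    label: str = ""
    subject_id: str = ""

    def __len__(self) -> int:
        return self.values.size


def _block_slice(block: Block, radius: int, height: int, width: int):
    """Code-map slice of coded pixels whose centers fall in ``block``."""
    r0 = max(block.r0, radius) - radius
    r1 = min(block.r1, height - radius) - radius
    c0 = max(block.c0, radius) - radius
    c1 = min(block.c1, width - radius) - radius
    return np.s_[r0:max(r1, r0), c0:max(c1, c0)]


def _block_hist(codes: np.ndarray, layout: PyramidLayout, radius: int,
                n_bins: int, normalize: bool) -> np.ndarray:
    out = np.empty((layout.n_blocks, n_bins))
    for b, block in enumerate(layout.blocks):
        sl = _block_slice(block, radius, layout.height, layout.width)
        h = np.bincount(codes[sl].ravel(), minlength=n_bins).astype(np.float64)
        if normalize and h.sum() > 0:
            h /= h.sum()
        out[b] = h
    return out


def ccentrist_descriptor(img, layout: PyramidLayout | None = None,
                         riu2: bool = True, normalize: bool = True,
                         m_threshold: str = "magnitude_mean") -> TextureDescriptor:
    """CLBP-based descriptor: per-block joint (S, M, C) histograms.

    Bins are flattened in (S, M, C) index order; 200 bins per block with
    riu2 (the default), 131072 without.
    """
    a = _as_array(img)
    if layout is None:
        layout = pyramid_blocks(*a.shape)
    s, m, c = clbp_codes(a, riu2=riu2, m_threshold=m_threshold)
    n_sm = s.n_codes
    joint = (s.codes * n_sm + m.codes) * 2 + c.codes
    hists = _block_hist(joint, layout, 1, n_sm * n_sm * 2, normalize)
    meta = img.meta if isinstance(img, SpectrogramImage) else {}
    return TextureDescriptor(hists.ravel(), "ccentrist",
                             meta.get("label", ""), meta.get("subject_id", ""))


def tcentrist_descriptor(img, layout: PyramidLayout | None = None,
                         mu: float = 5.0, normalize: bool = True) -> TextureDescriptor:
    """LTP-based descriptor: per-block upper + lower 256-bin histograms."""
    a = _as_array(img)
    if layout is None:
        layout = pyramid_blocks(*a.shape)
    upper, lower = ltp_codes(a, mu=mu)
    h_up = _block_hist(upper.codes, layout, 1, 256, normalize)
    h_lo = _block_hist(lower.codes, layout, 1, 256, normalize)
    hists = np.concatenate([h_up, h_lo], axis=1)  # per block: upper then lower
    meta = img.meta if isinstance(img, SpectrogramImage) else {}
    return TextureDescriptor(hists.ravel(), "tcentrist",
                             meta.get("label", ""), meta.get("subject_id", ""))


def centrist_descriptor(img, layout: PyramidLayout | None = None,
                        normalize: bool = True) -> TextureDescriptor:
    """Plain census-transform descriptor (baseline; 256 bins per block)."""
    a = _as_array(img)
    if layout is None:
        layout = pyramid_blocks(*a.shape)
    ct = census_transform(a)
    hists = _block_hist(ct.codes, layout, 1, 256, normalize)
    meta = img.meta if isinstance(img, SpectrogramImage) else {}
    return TextureDescriptor(hists.ravel(), "centrist",
                             meta.get("label", ""), meta.get("subject_id", ""))


def descriptor_length(extractor: str, layout: PyramidLayout,
                      riu2: bool = True) -> int:
    """Feature-vector length for a given extractor and pyramid layout."""
    per_block = {"ccentrist": (200 if riu2 else 131072),
                 "tcentrist": 512, "centrist": 256}[extractor]
    return layout.n_blocks * per_block


def extract_descriptor(img, extractor: str, layout: PyramidLayout | None = None,
                       riu2: bool = True, mu: float = 5.0,
                       normalize: bool = True) -> TextureDescriptor:
    """Dispatch on extractor name ("ccentrist" | "tcentrist" | "centrist")."""
    if extractor == "ccentrist":
        return ccentrist_descriptor(img, layout, riu2=riu2, normalize=normalize)
    if extractor == "tcentrist":
        return tcentrist_descriptor(img, layout, mu=mu, normalize=normalize)
    if extractor == "centrist":
        return centrist_descriptor(img, layout, normalize=normalize)
    raise ValidationError(f"unknown extractor '{extractor}'")
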