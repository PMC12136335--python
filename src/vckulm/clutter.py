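"""Spatiotemporal SVD clutter filtering.

Tissue clutter varies slowly in space and time, so in the Casorati matrix
(pixels × frames) of a temporal chunk it concentrates in the leading
singular components; zeroing those components isolates the fast, sparse
microbubble signal. A noise floor — estimated beforehand from a
bubble-free control acquisition — then suppresses residual noise so only
bubble-originated signal above the threshold is retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import FrameStack


@dataclass
class SVDConfig:
    n_tissue_components: int = 2   # leading singular components zeroed
    noise_threshold: float = 0.0   # post-filter magnitude floor
    chunk_size: int = 200          # frames per independent SVD block

    def __post_init__(self) -> None:
        if self.n_tissue_components < 0:
            raise ValueError("n_tissue_components must be nonnegative")
        if self.noise_threshold < 0:
            raise ValueError("noise_threshold must be nonnegative")
        if self.chunk_size < 2:
            raise ValueError("chunk_size must be >= 2")


def _filter_chunk(chunk: np.ndarray, n_remove: int, threshold: float) -> np.ndarray:
    n, rows, cols = chunk.shape
    casorati = chunk.reshape(n, rows * cols).T          # pixels × frames
    if n_remove == 0:
        out = np.abs(casorati)
    else:
        U, s, Vt = np.linalg.svd(casorati, full_matrices=False)
        k = min(n_remove, len(s))
        s = s.copy()
        s[:k] = 0.0
        out = np.abs(U @ (s[:, None] * Vt))
    if threshold > 0:
        out[out < threshold] = 0.0
    return out.T.reshape(n, rows, cols)


def svd_filter(stack: FrameStack, config: SVDConfig | None = None) -> FrameStack:
    """Remove tissue clutter chunk-wise and apply the noise floor.

    Each chunk of ``chunk_size`` frames is filtered independently: the
    Casorati matrix is formed, the leading ``n_tissue_components`` singular
    components are zeroed, the chunk is reconstructed, its magnitude taken
    (downstream localization needs nonnegative brightness), and pixels below
    ``noise_threshold`` are zeroed. Frame count and shape are preserved.
    """
    config = config or SVDConfig()
    frames = stack.frames
    if not np.all(np.isfinite(frames)):
        raise ValueError("input stack contains non-finite values")
    if stack.n_frames < 2:
        raise ValueError("need at least 2 frames")
    n_pixels = frames.shape[1] * frames.shape[2]
    if config.n_tissue_components >= min(n_pixels, config.chunk_size):
        raise ValueError("n_tissue_components must be < min(n_pixels, chunk_size)")
    out = np.empty_like(frames)
    for start in range(0, stack.n_frames, config.chunk_size):
        stop = min(start + config.chunk_size, stack.n_frames)
        if stop - start < 2:            # merge a trailing single frame
            start2 = max(stop - 2, 0)
            out[start:stop] = _filter_chunk(
                frames[start2:stop], config.n_tissue_components,
                config.noise_threshold)[start - start2:]
            continue
        out[start:stop] = _filter_chunk(
            frames[start:stop], config.n_tissue_components,
            config.noise_threshold)
    return stack.copy_with(frames=out)


def estimate_noise_threshold(control_stack: FrameStack,
                             config: SVDConfig | None = None,
                             percentile: float = 0.99) -> float:
    """Noise floor from a bubble-free control acquisition.

    Runs the SVD filter (without thresholding) on the control stack and
    returns the given percentile (fraction in [0, 1], default the 99th) of
    the residual magnitudes.
    """
    config = config or SVDConfig()
    if control_stack.frames.size == 0:
        raise ValueError("empty control stack")
    if not 0.0 <= percentile <= 1.0:
        raise ValueError("percentile must be a fraction in [0, 1]")
    cfg = SVDConfig(n_tissue_components=config.n_tissue_components,
                    noise_threshold=0.0, chunk_size=config.chunk_size)
    residual = svd_filter(control_stack, cfg).frames
    return float(np.quantile(np.abs(residual), percentile))
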