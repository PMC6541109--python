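"""NIfTI + FSL bval/bvec IO and voxelwise fitting of diffusion volumes."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

from .convergence import StoppingRule, classify_fiber_count
from .mcmc import MCMCConfig, run_simplified_mcmc, summarize_posterior
from .nuisance import estimate_nuisance
from .signal import make_scenario, predict_signal, add_noise
from .smoothing import SmoothingConfig
from .sphere import DWIProtocol, generate_hypothetical_directions, read_bvals_bvecs

__all__ = ["FitReport", "read_dwi", "fit_volume", "write_simulated_volume"]


@dataclass
class FitReport:
    """Per-voxel results of a volume fit; JSON-serializable."""

    voxels: list = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"config": self.config, "voxels": self.voxels}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FitReport":
        with open(path) as fh:
            d = json.load(fh)
        return cls(voxels=d["voxels"], config=d["config"])


def read_dwi(nifti_path, bval_path, bvec_path, mask_path=None):
    """Load a 4-D diffusion volume with its FSL-style gradient table.

    Returns ``(data, protocol, mask, affine)``; directions are renormalized
    (warning beyond 1e-3), all-zero vectors are accepted for b=0 volumes.
    """
    img = nib.load(str(nifti_path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 4:
        raise ValueError("expected a 4-D diffusion volume")
    bvals, bvecs = read_bvals_bvecs(bval_path, bvec_path)
    if bvals.size != data.shape[3]:
        raise ValueError(f"{bvals.size} b-values for {data.shape[3]} volumes")
    dirs = bvecs[bvals > 0]
    hyp = generate_hypothetical_directions(dirs) if len(dirs) else np.empty((0, 3))
    protocol = DWIProtocol(bvecs, bvals, hyp)
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).get_fdata()) > 0
    else:
        mask = np.ones(data.shape[:3], dtype=bool)
    return data, protocol, mask, img.affine


def fit_volume(data: np.ndarray, protocol: DWIProtocol,
               mask: np.ndarray | None = None,
               config: MCMCConfig | None = None,
               smoothing: SmoothingConfig | None = None,
               stopping_rule: StoppingRule | None = None,
               known_S0: float | None = None):
    """Fit the simplified model to every masked voxel.

    Pipeline per voxel: S0 from the b0 mean -> smoothing -> nuisance solve ->
    rotation -> adaptive MCMC with optional dynamic stopping -> fiber-count
    screen.  Isotropic voxels (F_hat ~ 0) are recorded as 0 fibers, not
    fatal.  Returns ``(report, maps)`` where ``maps`` holds 3-D parameter
    images (f1, f2, d, S0, n_fibers) and unit dyadic-vector images (z >= 0)
    per stick.
    """
    config = config or MCMCConfig(n_iter=20_000, thin=5)
    smoothing = smoothing or SmoothingConfig()
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    shape = data.shape[:3]
    maps = {k: np.zeros(shape) for k in ("f1", "f2", "d", "S0", "n_fibers")}
    maps["dyads1"] = np.zeros(shape + (3,))
    maps["dyads2"] = np.zeros(shape + (3,))
    report = FitReport(config={"n_iter": config.n_iter, "thin": config.thin,
                               "kappa": smoothing.kappa, "kappa2": smoothing.kappa2,
                               "seed": config.seed})
    for count, idx in enumerate(np.argwhere(mask)):
        i, j, k = map(int, idx)
        sig = data[i, j, k, :]
        rec = {"voxel": [i, j, k]}
        try:
            nuis = estimate_nuisance(sig, protocol, smoothing, known_S0=known_S0)
            rec["nuisance"] = nuis.to_dict()
            if nuis.F_hat <= 1e-6:
                rec["n_fibers"] = 0
            else:
                vcfg = replace(config, seed=config.seed + count)
                chain = run_simplified_mcmc(sig, protocol, nuis, vcfg,
                                            stopping_rule=stopping_rule)
                summ = summarize_posterior(chain, vcfg, nuis)
                rec["n_fibers"] = classify_fiber_count(chain, nuis, vcfg)
                rec["median"] = {p: summ.median[p] for p in
                                 ("f1", "f2", "sigma", "phi1p", "phi2p")}
                rec["sd"] = {p: summ.sd[p] for p in ("f1", "f2", "sigma")}
                rec["stopped_at"] = chain.stopped_at
                rec["accept_rate"] = [float(a) for a in chain.accept_rate]
                maps["f1"][i, j, k] = summ.fractions[0]
                maps["f2"][i, j, k] = summ.fractions[1]
                for fi, key in enumerate(("dyads1", "dyads2")):
                    maps[key][i, j, k] = summ.directions[fi]
            maps["d"][i, j, k] = nuis.d_hat
            maps["S0"][i, j, k] = nuis.S0_hat
            maps["n_fibers"][i, j, k] = rec["n_fibers"]
        except Exception as exc:  # noqa: BLE001 - per-voxel failure is data
            rec["error"] = repr(exc)
        report.voxels.append(rec)
    return report, maps


def write_simulated_volume(out_prefix, scenario: str = "paper-default-64",
                           shape: tuple[int, int, int] = (2, 2, 1),
                           seed: int = 0):
    """Write a synthetic NIfTI volume (every voxel = scenario truth) + bval/bvec."""
    from .sphere import write_bvals_bvecs

    truth, protocol = make_scenario(scenario)
    clean = predict_signal(truth, protocol)
    n = len(protocol)
    data = np.empty(shape + (n,))
    for c, idx in enumerate(np.ndindex(shape)):
        data[idx] = add_noise(clean, truth.sigma,
                              int(np.random.SeedSequence([seed, c]).generate_state(1)[0]
                                  & 0x7FFFFFFF))
    img = nib.Nifti1Image(data.astype(np.float32), np.eye(4))
    nib.save(img, f"{out_prefix}.nii")
    write_bvals_bvecs(f"{out_prefix}.bval", f"{out_prefix}.bvec",
                      protocol.bvals, protocol.bvecs)
    return f"{out_prefix}.nii", f"{out_prefix}.bval", f"{out_prefix}.bvec"
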