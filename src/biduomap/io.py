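"""Persistence of posterior draws and run metadata (CSV/JSON only)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .mcmc import PosteriorDraws, rhat_table
from .models import model_registry
from .spatial import DISEASES

__all__ = ["save_draws", "load_draws"]


def save_draws(draws: PosteriorDraws, outdir) -> None:
    """Write one parameter CSV per chain, the log-likelihood and log-RR draws,
    and a metadata JSON (seed, acceptance rates, R-hat table)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for c in range(draws.n_chains):
        cols = {nm: draws.scalars[nm][c] for nm in sorted(draws.scalars)}
        for nm in sorted(draws.fields):
            for i, a in enumerate(draws.area_ids):
                cols[f"{nm}[{a}]"] = draws.fields[nm][c, :, i]
        for k in DISEASES:
            for i, a in enumerate(draws.area_ids):
                cols[f"log_theta_{k}[{a}]"] = draws.log_theta[k][c, :, i]
        pd.DataFrame(cols).to_csv(outdir / f"chain{c}.csv", index=False)
        pd.DataFrame(
            draws.loglik[c], columns=[f"{a}:{k}" for a, k in draws.obs_index]
        ).to_csv(outdir / f"loglik_chain{c}.csv", index=False)
    meta = {
        "model": draws.spec.name,
        "area_ids": list(draws.area_ids),
        "n_chains": draws.n_chains,
        "n_iter": draws.n_iter,
        "burn_in": draws.burn_in,
        "thin": draws.thin,
        "seed": draws.seed,
        "acceptance": draws.acceptance,
        "rhat": rhat_table(draws) if draws.n_chains >= 2 and draws.n_draws >= 10 else {},
    }
    with open(outdir / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def load_draws(outdir) -> PosteriorDraws:
    outdir = Path(outdir)
    with open(outdir / "metadata.json") as fh:
        meta = json.load(fh)
    spec = model_registry(meta["model"])
    area_ids = tuple(meta["area_ids"])
    n_chains = meta["n_chains"]
    chains = [pd.read_csv(outdir / f"chain{c}.csv") for c in range(n_chains)]
    logliks = [pd.read_csv(outdir / f"loglik_chain{c}.csv") for c in range(n_chains)]
    obs_index = [tuple(col.rsplit(":", 1)) for col in logliks[0].columns]
    scalar_names = [c for c in chains[0].columns if "[" not in c]
    field_names = sorted(
        {c.split("[")[0] for c in chains[0].columns if "[" in c and not c.startswith("log_theta")}
    )
    scalars = {nm: np.stack([ch[nm].to_numpy() for ch in chains]) for nm in scalar_names}
    fields = {
        nm: np.stack(
            [ch[[f"{nm}[{a}]" for a in area_ids]].to_numpy() for ch in chains]
        )
        for nm in field_names
    }
    log_theta = {
        k: np.stack(
            [ch[[f"log_theta_{k}[{a}]" for a in area_ids]].to_numpy() for ch in chains]
        )
        for k in DISEASES
    }
    loglik = np.stack([ll.to_numpy() for ll in logliks])
    return PosteriorDraws(
        spec=spec,
        area_ids=area_ids,
        obs_index=obs_index,
        scalars=scalars,
        fields=fields,
        log_theta=log_theta,
        loglik=loglik,
        acceptance=meta.get("acceptance", {}),
        seed=meta["seed"],
        n_iter=meta["n_iter"],
        burn_in=meta["burn_in"],
        thin=meta["thin"],
    )
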