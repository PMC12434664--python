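"""End-to-end pipeline orchestration.

``run_pipeline`` executes the stages in dependency order — structural
model, ensemble generation, reaction coordinates, then the three analysis
branches (projection, ion statistics, interaction maps) and the umbrella
sampling / WHAM branch — writing every artifact as plain text with the
run's seed and config hash stamped in a header line, plus a JSON manifest
with a content hash per file.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from pathlib import Path

import numpy as np
import yaml

from . import cg_sim, coords, datasets, elvim, ions, pairs, rna_model, wham

__all__ = ["demo_config", "validate_config", "run_pipeline", "load_config"]

ALL_STAGES = ("model", "sim", "coords", "elvim", "ions", "pairs", "wham")


def demo_config() -> dict:
    """The bundled demo: a 12-nt toy hairpin, a 200-frame morph ensemble
    with a scripted ion bridge, and a 9-window umbrella run."""
    return {
        "seed": 1,
        "synthetic": {"kind": "toy_hairpin"},
        "contacts": {"cutoff": 7.0, "min_sep": 3},
        "morph": {
            "n_frames": 200,
            "unfold_fraction": 1.0,
            "noise": 0.4,
            "n_background_ions": 3,
            "bridge": {"res_i": 2, "res_j": 11, "fraction": 0.7},
        },
        "elvim": {"sigma0": 3.0, "eps": 0.15, "n_iter": 60,
                  "step_fraction": 0.125},
        "ions": {"cutoff": 8.0, "q_bin": 0.05, "min_sep": 4},
        "pairs": {"lambda": 1.2, "q_bin": 0.1},
        "umbrella": {
            "n_windows": 9, "k_q": 200.0, "n_steps": 3000,
            "save_interval": 10, "temperature": 1.0, "n_bins": 40,
        },
    }


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def validate_config(config: dict) -> None:
    has_structure = "structure" in config
    has_synthetic = "synthetic" in config
    if has_structure == has_synthetic:
        raise ValueError(
            "config must provide exactly one of a 'structure' input block "
            "or a 'synthetic' generator block"
        )


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()
    ).hexdigest()[:16]


def _log(msg: str, **kv) -> None:
    stamp = time.strftime("%Y-%m-%dT%H:%M:%S")
    extra = " ".join(f"{k}={v}" for k, v in kv.items())
    print(f"{stamp} {msg} {extra}".rstrip(), file=sys.stderr)


class _Writer:
    def __init__(self, out_dir: Path, header: str):
        self.out_dir = out_dir
        self.header = header
        self.files: dict[str, str] = {}

    def write(self, name: str, text: str, stamp: bool = True) -> Path:
        path = self.out_dir / name
        body = (self.header + text) if stamp else text
        path.write_text(body)
        self.files[name] = hashlib.sha256(body.encode()).hexdigest()
        return path


def run_pipeline(
    config: dict,
    out_dir: str | Path,
    stages: tuple[str, ...] | None = None,
) -> dict:
    """Run the configured stages and return the manifest dict.

    Analysis stages pull in their prerequisites automatically, so asking
    for ``("ions",)`` still builds the model and the ensemble first.
    Identical (config, seed) runs produce byte-identical artifacts.
    """
    validate_config(config)
    requested = set(stages or ALL_STAGES)
    unknown = requested - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    # dependency closure: everything downstream needs model+sim+coords
    if requested - {"model"}:
        requested |= {"model", "sim", "coords"}

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    chash = _config_hash(config)
    w = _Writer(out_dir, header=f"# config_hash={chash}\tseed={seed}\n")
    manifest: dict = {"config_hash": chash, "seed": seed, "stages": [],
                      "files": w.files}

    def done(stage: str) -> None:
        manifest["stages"].append(stage)
        _log("stage complete", stage=stage)

    try:
        # ---- model -------------------------------------------------------
        if "synthetic" in config:
            kind = config["synthetic"].get("kind", "toy_hairpin")
            if kind == "toy_hairpin":
                cg, ann = datasets.toy_hairpin()
            elif kind == "riboswitch":
                cg, ann = datasets.synthetic_riboswitch()
            else:
                raise ValueError(f"unknown synthetic kind {kind!r}")
        else:
            sblock = config["structure"]
            pdb_text = Path(sblock["pdb"]).read_text()
            struct = rna_model.load_structure(
                pdb_text, chain_id=sblock.get("chain", "A"),
                source_id=sblock["pdb"],
            )
            cg = rna_model.coarse_grain(struct)
            ann_path = sblock.get("annotations")
            ann = (
                rna_model.read_annotations(Path(ann_path).read_text(),
                                           n_residues=cg.n_residues)
                if ann_path
                else rna_model.AnnotationList([], [], cg.n_residues)
            )
        cblock = config.get("contacts", {})
        nc = rna_model.native_contacts(
            cg, cutoff=cblock.get("cutoff", 7.0),
            min_sep=cblock.get("min_sep", 3),
        )
        w.write("cg_structure.pdb", cg.to_pdb(), stamp=False)
        w.write("native_contacts.tsv", nc.to_tsv())
        w.write("annotations.tsv", rna_model.write_annotations(ann))
        done("model")
        if requested == {"model"}:
            raise _Stop

        # ---- sim (morph ensemble) ----------------------------------------
        mblock = config.get("morph", {})
        bridge = None
        if mblock.get("bridge"):
            bb = mblock["bridge"]
            bridge = cg_sim.BridgeSpec(
                res_i=bb["res_i"], res_j=bb["res_j"],
                fraction=bb.get("fraction", 0.7),
            )
        traj = cg_sim.morph_ensemble(
            cg,
            n_frames=mblock.get("n_frames", 200),
            unfold_fraction=mblock.get("unfold_fraction", 1.0),
            noise=mblock.get("noise", 0.4),
            seed=seed,
            n_background_ions=mblock.get("n_background_ions", 3),
            bridge=bridge,
        )
        done("sim")

        # ---- coords --------------------------------------------------------
        q = coords.q_series(traj.rna, nc)
        w.write("q_series.tsv", coords.q_series_to_tsv(q, contact_set_id=chash))
        done("coords")

        # ---- elvim ---------------------------------------------------------
        if "elvim" in requested:
            eblock = config.get("elvim", {})
            D = elvim.dissimilarity_matrix(
                traj.rna, cg.bead_residues,
                sigma0=eblock.get("sigma0", 3.0), eps=eblock.get("eps", 0.15),
            )
            emb = elvim.force_scheme(
                D, n_iter=eblock.get("n_iter", 100),
                step_fraction=eblock.get("step_fraction", 0.125), seed=seed,
            )
            elvim.kde_density(emb)
            rmsds = np.array([coords.rmsd(f, cg.xyz) for f in traj.rna])
            w.write("embedding.tsv", emb.to_tsv(q=q, rmsd=rmsds))
            done("elvim")

        # ---- ions ----------------------------------------------------------
        if "ions" in requested:
            iblock = config.get("ions", {})
            cutoff = iblock.get("cutoff")
            rdf = ions.rdf_mg_phosphate(traj)
            if cutoff is None:
                cutoff = rdf.first_minimum or ions.DEFAULT_CUTOFF
            counts = ions.occupancy(traj, cutoff=cutoff)
            heat = ions.occupancy_vs_q(counts, q,
                                       bin_width=iblock.get("q_bin", 0.05),
                                       cutoff=cutoff)
            bmap = ions.bridging_map(traj, cutoff=cutoff,
                                     min_sep=iblock.get("min_sep", 4))
            w.write("rdf.tsv", rdf.to_tsv())
            w.write("occupancy_heatmap.tsv", heat.to_tsv())
            w.write("bridge_map.tsv", bmap.to_tsv())
            done("ions")

        # ---- pairs ---------------------------------------------------------
        if "pairs" in requested and ann.n_interactions:
            pblock = config.get("pairs", {})
            states = pairs.interaction_states(
                traj.rna, cg, ann, lam=pblock.get("lambda", 1.2)
            )
            freq, _ = pairs.frequency_vs_q(
                states, q, bin_width=pblock.get("q_bin", 0.1)
            )
            labels = ann.labels()
            lines = ["Q_bin\t" + "\t".join(labels)]
            nb = freq.shape[0]
            for b in range(nb):
                row = "\t".join(
                    "NA" if np.isnan(v) else f"{v:.4f}" for v in freq[b]
                )
                lines.append(f"{(b + 0.5) / nb:.3f}\t{row}")
            w.write("pair_frequency_vs_q.tsv", "\n".join(lines) + "\n")
            emap = pairs.ensemble_map(states, n_residues=cg.n_residues)
            lines = ["\t".join(f"{v:.4f}" for v in row) for row in emap]
            w.write("interaction_map.tsv", "\n".join(lines) + "\n")
            done("pairs")

        # ---- wham ----------------------------------------------------------
        if "wham" in requested:
            ublock = config.get("umbrella", {})
            n_win = ublock.get("n_windows", 9)
            q0s = np.linspace(0.1, 0.9, n_win)
            cfg = cg_sim.SimConfig(
                n_steps=ublock.get("n_steps", 3000),
                save_interval=ublock.get("save_interval", 10),
                temperature=ublock.get("temperature", 1.0),
                timestep=ublock.get("timestep", 0.01),
                seed=seed,
            )
            top = cg_sim.build_topology(cg, nc, cfg)
            wins, trajs = [], []
            for wdx, q0 in enumerate(q0s):
                win = cg_sim.UmbrellaWindow(
                    q0=float(q0), k_q=ublock.get("k_q", 200.0), window_id=wdx
                )
                wcfg = cg_sim.SimConfig(**{**cfg.__dict__, "seed": seed + wdx})
                trajs.append(cg_sim.umbrella_run(top, wcfg, win, x0_rna=cg.xyz))
                wins.append(win)
            hists, biases, centers = wham.umbrella_histograms(
                trajs, wins, n_bins=ublock.get("n_bins", 40),
                burn_in=ublock.get("burn_in", 5),
            )
            profile = wham.wham_solve(hists, biases,
                                      temperature=cfg.temperature,
                                      q_grid=centers)
            w.write("free_energy_profile.tsv", profile.to_tsv())
            sidecar = {
                "windows": [
                    {"window_id": win.window_id, "q0": win.q0, "k_q": win.k_q}
                    for win in wins
                ],
                "residual": profile.residual,
                "n_iter": profile.n_iter,
                "seed": seed,
                "config_hash": chash,
            }
            w.write("wham_windows.json", json.dumps(sidecar, indent=1),
                    stamp=False)
            done("wham")
    except _Stop:
        pass
    except Exception:
        manifest["status"] = "failed"
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise

    manifest["status"] = "ok"
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


class _Stop(Exception):
    """Internal: requested stages complete."""
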