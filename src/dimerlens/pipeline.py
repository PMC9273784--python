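"""End-to-end analysis pipeline: snapshots in, tables and manifest out.

Stages run in order: read (or generate) the ensemble, classify dimers,
contact statistics and effective landscape, secondary structure, native
fibril contacts, experiment-facing observables.  Every output is a TSV
table plus a JSON manifest holding parameters, seeds and counts; a
fixed seed reproduces every output byte for byte.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd

from . import contacts as ct
from . import cutabi as ss
from . import fibril as fb
from . import observables as obs
from .constants import (CONTACT_CUTOFF, DIMER_CUTOFF, NFC_CUTOFF,
                        SS_REGION)
from .io_ensemble import EnsembleHandle, read_structures
from .synthetic import DimerPlantSpec, EnsembleSpec, SegmentSpec, \
    sample_ensemble

__all__ = ["run_pipeline"]


class PipelineError(RuntimeError):
    pass


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as err:
                raise PipelineError(f"stage {name!r} failed: {err}") \
                    from err
        return wrapped
    return deco


def _ensemble_from_config(config: dict) -> tuple[EnsembleHandle,
                                                 pd.DataFrame | None]:
    if "input" in config:
        return (read_structures(config["input"],
                                config.get("format")), None)
    syn = dict(config["synthetic"])
    if "seed" in config:
        syn.setdefault("seed", config["seed"])
    for key, cls in (("dfncs_interface", DimerPlantSpec),
                     ("dimer_interface", DimerPlantSpec)):
        if key in syn and isinstance(syn[key], dict):
            syn[key] = cls(**syn[key])
    for key in ("segments_a", "segments_b"):
        if key in syn:
            syn[key] = tuple(SegmentSpec(**s) if isinstance(s, dict)
                             else s for s in syn[key])
    if "rg_mixture" in syn:
        syn["rg_mixture"] = tuple(tuple(c) for c in syn["rg_mixture"])
    return sample_ensemble(EnsembleSpec(**syn))


def _write_tsv(df: pd.DataFrame, outdir: str, name: str) -> str:
    # the manifest records basenames so that seeded re-runs into
    # different directories stay byte-identical
    df.to_csv(os.path.join(outdir, name), sep="\t", index=False,
              float_format="%.6g")
    return name


def run_pipeline(config: dict) -> dict:
    """Run every analysis stage and write tables under ``outdir``.

    ``config`` needs ``outdir`` and either ``input`` (a PDB/XYZ path)
    or ``synthetic`` (keyword arguments of
    :class:`~dimerlens.synthetic.EnsembleSpec`).  Optional keys:
    ``seed``, ``contact_cutoff``, ``dimer_cutoff``, ``nfc_cutoff``,
    ``min_seq_sep``, ``bin_width``, ``region``, ``fret_residue``,
    ``fret_r0``, ``fret_offset``.  Returns the manifest dict (also
    written as ``manifest.json``).
    """
    missing = [k for k in ("outdir",) if k not in config]
    if "input" not in config and "synthetic" not in config:
        missing.append("input|synthetic")
    if missing:
        raise PipelineError(f"config is missing keys: {missing}")

    outdir = config["outdir"]
    os.makedirs(outdir, exist_ok=True)
    contact_cutoff = config.get("contact_cutoff", CONTACT_CUTOFF)
    dimer_cutoff = config.get("dimer_cutoff", DIMER_CUTOFF)
    nfc_cutoff = config.get("nfc_cutoff", NFC_CUTOFF)
    min_seq_sep = config.get("min_seq_sep", 1)
    bin_width = config.get("bin_width", 5.0)
    region = tuple(config.get("region", SS_REGION))
    fret_residue = config.get("fret_residue", 90)
    fret_r0 = config.get("fret_r0", 60.0)
    fret_offset = config.get("fret_offset", 20.0)

    manifest: dict = {
        "parameters": {
            "contact_cutoff": contact_cutoff,
            "dimer_cutoff": dimer_cutoff,
            "nfc_cutoff": nfc_cutoff,
            "min_seq_sep": min_seq_sep,
            "bin_width": bin_width,
            "region": list(region),
            "fret_residue": fret_residue,
            "fret_r0": fret_r0,
            "fret_offset": fret_offset,
            "seed": config.get("seed"),
        },
        "outputs": [],
    }

    ensemble, truth = _stage("read")(_ensemble_from_config)(config)
    manifest["n_snapshots"] = ensemble.count
    manifest["provenance"] = ensemble.provenance
    if truth is not None:
        manifest["outputs"].append(
            _write_tsv(truth, outdir, "ground_truth.tsv"))

    # --- dimer classification -------------------------------------------
    @_stage("classify_dimers")
    def classify():
        labels = [ct.classify_dimer(conf, cutoff=dimer_cutoff)
                  for conf in ensemble]
        idx = [i for i, lb in enumerate(labels) if lb.is_dimer]
        return labels, idx

    dimer_labels, dimer_idx = classify()
    n_dimers = len(dimer_idx)
    manifest["n_dimers"] = n_dimers
    manifest["dimer_fraction"] = n_dimers / ensemble.count

    if n_dimers == 0:
        manifest["note"] = "no dimers found; dimer stages skipped"
        _finish(manifest, outdir)
        return manifest
    dimers = ensemble.subset(dimer_idx, tag="dimers")

    # --- contacts and landscape -----------------------------------------
    @_stage("contacts")
    def contact_stage():
        sets = [ct.compute_contacts(conf, cutoff=contact_cutoff,
                                    min_seq_sep=min_seq_sep)
                for conf in dimers]
        samples = [(s.n_inter, s.n_intra) for s in sets]
        grid = ct.effective_landscape(samples, bin_width=bin_width)
        minima = ct.find_minima(grid)
        profile = ct.mean_intermolecular_contacts(
            dimers, cutoff=contact_cutoff)
        inter_map, intra_map = ct.contact_probability_maps(
            dimers, cutoff=contact_cutoff, min_seq_sep=min_seq_sep)
        return samples, grid, minima, profile, inter_map, intra_map

    samples, grid, minima, profile, inter_map, intra_map = contact_stage()
    occ = np.argwhere(grid.P > 0)
    manifest["outputs"] += [
        _write_tsv(pd.DataFrame(
            {"n_inter": [s[0] for s in samples],
             "n_intra": [s[1] for s in samples]}),
            outdir, "contact_counts.tsv"),
        _write_tsv(pd.DataFrame(
            {"n_inter": grid.x_centers[occ[:, 0]],
             "n_intra": grid.y_centers[occ[:, 1]],
             "P": grid.P[occ[:, 0], occ[:, 1]],
             "F": grid.F[occ[:, 0], occ[:, 1]]}),
            outdir, "landscape.tsv"),
        _write_tsv(pd.DataFrame(minima,
                                columns=["n_inter", "n_intra", "F"]),
                   outdir, "landscape_minima.tsv"),
        _write_tsv(pd.DataFrame(
            {"residue": np.arange(1, len(profile) + 1),
             "mean_inter_contacts": profile}),
            outdir, "mean_contacts.tsv"),
        _write_tsv(pd.DataFrame(inter_map), outdir,
                   "contact_map_inter.tsv"),
        _write_tsv(pd.DataFrame(intra_map), outdir,
                   "contact_map_intra.tsv"),
    ]

    # --- secondary structure --------------------------------------------
    @_stage("secondary_structure")
    def ss_stage():
        assignments = [ss.assign_ss(conf) for conf in dimers]
        nfc_vectors = [fb.native_fibril_contacts(conf, cutoff=nfc_cutoff)
                       for conf in dimers]
        n_res = dimers[0].chains[0].n_residues
        p_helix = np.zeros(n_res)
        p_intra = np.zeros(n_res)
        p_inter = np.zeros(n_res)
        p_nfc = np.zeros(n_res)
        for asg, nfc in zip(assignments, nfc_vectors):
            for cid, lab in asg.labels.items():
                p_helix += (lab == "H") / 2.0
                intra = {r for (c, r) in
                         asg.residues_in_sheets(scope="intra") if c == cid}
                inter = {r for (c, r) in
                         asg.residues_in_sheets(scope="inter") if c == cid}
                for r in intra:
                    p_intra[r - 1] += 0.5
                for r in inter:
                    p_inter[r - 1] += 0.5
            p_nfc += nfc
        counts = [ss.count_ss_region(a, region) for a in assignments]
        states, b_density, hb_density = ss.split_B_HB(counts)
        orient = ss.orientation_percentages(assignments)
        return (assignments, counts, states, b_density, hb_density,
                orient, p_helix / len(assignments),
                p_intra / len(assignments), p_inter / len(assignments),
                p_nfc / len(assignments))

    (assignments, counts, states, b_density, hb_density, orient,
     p_helix, p_intra, p_inter, p_nfc) = ss_stage()
    manifest["outputs"].append(_write_tsv(pd.DataFrame(
        {"residue": np.arange(1, len(p_helix) + 1),
         "P_helix": p_helix, "P_intra_sheet": p_intra,
         "P_inter_sheet": p_inter, "P_nfc": p_nfc}),
        outdir, "ss_profiles.tsv"))
    manifest["outputs"].append(_write_tsv(pd.DataFrame(
        {"alpha": [c.alpha for c in counts],
         "beta": [c.beta for c in counts],
         "state": states}), outdir, "ss_counts.tsv"))
    manifest["state_B_fraction"] = float(np.mean(states == "B"))
    manifest["sheet_percentages"] = {
        "parallel": orient.parallel,
        "antiparallel": orient.antiparallel,
        **orient.by_scope}

    # --- native fibril contacts -----------------------------------------
    @_stage("native_fibril_contacts")
    def nfc_stage():
        dlabels = [fb.classify_dfncs(conf, cutoff=nfc_cutoff)
                   for conf in dimers]
        prof, best = fb.nfc_profile(dimers, cutoff=nfc_cutoff)
        return dlabels, prof, best

    dlabels, nfc_prof, best_run = nfc_stage()
    n_dfncs = sum(lb.is_dfncs for lb in dlabels)
    manifest["n_dfncs"] = int(n_dfncs)
    manifest["dfncs_fraction_of_dimers"] = n_dfncs / n_dimers
    manifest["dfncs_pct_of_dimers"] = 100.0 * n_dfncs / n_dimers
    manifest["max_nfc_run"] = best_run
    if best_run["start"] is not None:
        manifest["contour_length_at_max_run"] = \
            fb.contour_length_estimate(best_run["start"])
    manifest["outputs"].append(_write_tsv(pd.DataFrame(
        {"residue": np.arange(1, len(nfc_prof) + 1),
         "P_nfc": nfc_prof}), outdir, "nfc_profile.tsv"))

    # --- observables -----------------------------------------------------
    @_stage("observables")
    def observables_stage():
        rg_dimer = [obs.radius_of_gyration(conf, "dimer")
                    for conf in dimers]
        rg_chain = [obs.radius_of_gyration(conf, "chain",
                                           chain_id=ch.chain_id)
                    for conf in ensemble for ch in conf.chains]
        gmm = None
        if len(rg_chain) >= 50:
            gmm = obs.fit_rg_mixture(rg_chain,
                                     seed=config.get("seed", 0) or 0)
        dists = obs.residue_pair_distance_distribution(
            dimers, residue=fret_residue)
        return rg_dimer, rg_chain, gmm, dists

    rg_dimer, rg_chain, gmm, dists = observables_stage()
    manifest["rg_dimer_mean"] = float(np.mean(rg_dimer))
    manifest["rg_chain_mean"] = float(np.mean(rg_chain))
    if gmm is not None:
        manifest["rg_gmm"] = {
            "n_components": gmm.n_components,
            "components": gmm.components,
            "ensemble_average": gmm.ensemble_average}
    manifest["outputs"].append(_write_tsv(pd.DataFrame(
        {"rg_dimer": rg_dimer}), outdir, "rg_dimer.tsv"))
    fret_rows = []
    for key, arr in dists.items():
        for d in arr:
            rec = obs.fret_efficiency(d, r0=fret_r0, offset=fret_offset)
            fret_rows.append({"subpopulation": key, "ca_distance": d,
                              "efficiency": rec.efficiency})
    manifest["outputs"].append(_write_tsv(
        pd.DataFrame(fret_rows,
                     columns=["subpopulation", "ca_distance",
                              "efficiency"]),
        outdir, "fret_efficiency.tsv"))

    _finish(manifest, outdir)
    return manifest


def _finish(manifest: dict, outdir: str) -> None:
    path = os.path.join(outdir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    manifest["manifest_path"] = path
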