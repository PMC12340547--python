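"""Reader/writer for the MEME minimal motif text format.

Only the subset needed for PWM exchange is supported: version line,
alphabet, strand line, 0-order background frequencies and
letter-probability matrices.
"""

from __future__ import annotations

import numpy as np

from .motif_discovery import MotifModel


def write_meme(models: list[MotifModel], path: str, names: list[str] | None = None) -> None:
    if names is None:
        names = [f"motif_{i + 1}" for i in range(len(models))]
    bg = models[0].background if models else np.full(4, 0.25)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\n")
        fh.write("ALPHABET= ACGT\n\n")
        fh.write("strands: +\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            "A {:.6f} C {:.6f} G {:.6f} T {:.6f}\n\n".format(*bg)
        )
        for model, name in zip(models, names):
            nsites = max(1, round(model.gamma * model.n_training_sequences))
            fh.write(f"MOTIF {name} {model.consensus}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {model.width} "
                f"nsites= {nsites} E= 0\n"
            )
            for col in model.theta.T:
                fh.write(" {:.6f} {:.6f} {:.6f} {:.6f}\n".format(*col))
            fh.write("\n")


def read_meme(path: str) -> list[MotifModel]:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    background = np.full(4, 0.25)
    models: list[MotifModel] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            toks = lines[i + 1].split()
            background = np.array([float(toks[j]) for j in (1, 3, 5, 7)])
            i += 2
            continue
        if line.startswith("MOTIF"):
            j = i + 1
            while j < len(lines) and "letter-probability matrix" not in lines[j]:
                j += 1
            if j == len(lines):
                raise ValueError(f"MOTIF at line {i + 1} has no probability matrix")
            header = lines[j]
            w = int(header.split("w=")[1].split()[0])
            nsites = int(header.split("nsites=")[1].split()[0]) if "nsites=" in header else 1
            rows = []
            for k in range(j + 1, j + 1 + w):
                rows.append([float(tok) for tok in lines[k].split()])
            theta = np.array(rows).T
            theta = theta / theta.sum(axis=0, keepdims=True)
            models.append(
                MotifModel(
                    width=w,
                    theta=theta,
                    background=background / background.sum(),
                    gamma=1.0,
                    n_training_sequences=nsites,
                )
            )
            i = j + 1 + w
            continue
        i += 1
    return models
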