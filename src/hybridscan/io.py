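"""Plain-text tables with self-describing comment headers.

The polarized-site table is the interchange format between pipeline stages:
a tab-separated file whose leading ``#`` comment lines carry the ingroup
order, contig lengths and (when produced by a pipeline run) the config
hash, so downstream stages need no side-channel metadata.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd


def write_sites_table(
    sites: pd.DataFrame,
    path: str,
    ingroup: Sequence[str],
    contig_lengths: Mapping[str, int] | None = None,
    extra_comments: Sequence[str] = (),
) -> None:
    with open(path, "w") as fh:
        fh.write("# hybridscan polarized sites\n")
        fh.write(f"# ingroup={','.join(ingroup)}\n")
        if contig_lengths:
            for name, length in contig_lengths.items():
                fh.write(f"# contig={name}:{int(length)}\n")
        for line in extra_comments:
            fh.write(f"# {line}\n")
        sites.to_csv(fh, sep="\t", index=False)


def read_sites_table(path: str) -> tuple[pd.DataFrame, list[str], dict[str, int]]:
    ingroup: list[str] = []
    contig_lengths: dict[str, int] = {}
    n_comments = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_comments += 1
            body = line[1:].strip()
            if body.startswith("ingroup="):
                ingroup = body.split("=", 1)[1].split(",")
            elif body.startswith("contig="):
                name, length = body.split("=", 1)[1].rsplit(":", 1)
                contig_lengths[name] = int(length)
    sites = pd.read_csv(path, sep="\t", skiprows=n_comments)
    return sites, ingroup, contig_lengths


def write_table(df: pd.DataFrame, path: str, comments: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
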