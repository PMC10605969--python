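"""On-disk serialization: a versioned directory of flat arrays + metadata.

The directory stores the pan-genome text, the index parameters and the graph
components.  Loading rebuilds the rank structures deterministically from the
stored text and parameters, which round-trips bit-exactly.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np

from .fmindex import BidirectionalIndex, build_index
from .graph import GraphNode, ImplicitGraph
from .pantext import PanGenomeText

FORMAT_VERSION = 1


def save_dataset(
    directory,
    text: PanGenomeText,
    index: BidirectionalIndex,
    graph: ImplicitGraph | None = None,
    n_replacement_seed: int | None = None,
) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": FORMAT_VERSION,
        "s_sa": index.s_sa,
        "seq_names": text.seq_names,
        "seq_starts": text.seq_starts,
        "n_replacement_seed": n_replacement_seed,
    }
    if graph is not None:
        meta["k"] = graph.k
        meta["s_cp"] = (
            None if graph.s_cp is None
            else ("inf" if graph.s_cp == math.inf else int(graph.s_cp))
        )
    (d / "text.txt").write_text(text.T)
    if graph is not None:
        np.savez(
            d / "graph.npz",
            node_len=np.array([nd.len for nd in graph.nodes], dtype=np.int64),
            node_mult=np.array([nd.mult for nd in graph.nodes], dtype=np.int64),
            node_left=np.array([nd.left_kmer for nd in graph.nodes], dtype=np.int64),
            node_rkr=np.array([nd.right_kmer_r for nd in graph.nodes], dtype=np.int64),
            node_end=np.array([nd.is_end for nd in graph.nodes], dtype=bool),
            node_seq=np.array(
                [-1 if nd.seq is None else nd.seq for nd in graph.nodes],
                dtype=np.int64,
            ),
            B=graph.B,
            B_r=graph.B_r,
            idmap_id=np.array([i for i, _ in graph.idmap], dtype=np.int64),
            idmap_off=np.array([o for _, o in graph.idmap], dtype=np.int64),
            idmap_r=np.array(graph.idmap_r, dtype=np.int64),
        )
    (d / "meta.json").write_text(json.dumps(meta, indent=1))


def load_dataset(directory):
    """Returns ``(text, index, graph_or_None)``."""
    d = Path(directory)
    meta = json.loads((d / "meta.json").read_text())
    if meta["format_version"] != FORMAT_VERSION:
        raise ValueError(f"unsupported index format {meta['format_version']}")
    text = PanGenomeText(
        T=(d / "text.txt").read_text(),
        seq_names=list(meta["seq_names"]),
        seq_starts=list(meta["seq_starts"]),
    )
    index = build_index(text, s_sa=meta["s_sa"])
    graph = None
    gpath = d / "graph.npz"
    if gpath.exists():
        z = np.load(gpath)
        nodes = [
            GraphNode(
                len=int(z["node_len"][i]),
                mult=int(z["node_mult"][i]),
                left_kmer=int(z["node_left"][i]),
                right_kmer_r=int(z["node_rkr"][i]),
                is_end=bool(z["node_end"][i]),
                seq=None if z["node_seq"][i] < 0 else int(z["node_seq"][i]),
            )
            for i in range(z["node_len"].size)
        ]
        raw_cp = meta["s_cp"]
        s_cp = None if raw_cp is None else (math.inf if raw_cp == "inf" else int(raw_cp))
        graph = ImplicitGraph(
            nodes=nodes,
            B=z["B"],
            B_r=z["B_r"],
            idmap=list(zip(z["idmap_id"].tolist(), z["idmap_off"].tolist())),
            idmap_r=z["idmap_r"].tolist(),
            k=int(meta["k"]),
            s_cp=s_cp,
            S=text.S,
        )
    return text, index, graph
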