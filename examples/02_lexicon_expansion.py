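"""Expand a seed lexicon with CBOW embeddings on a planted corpus.

The co-occurrence generator emits seed words and their synonyms inside the
same context templates and distractors in disjoint ones; after CBOW
training, the synonyms should top the similarity ranking to the seeds.
"""

import hpagtwr as h

seeds = ["seed1", "seed2"]
synonyms = ["syn1", "syn2"]
distractors = ["bad1", "bad2"]

corpus = h.generate_cooccurrence_corpus(seeds, synonyms, distractors,
                                        n_sentences=500, seed=3)
emb = h.train_embeddings(corpus, dim=50, window=5, epochs=20, min_count=5,
                         seed=4)
candidates = h.expand_seed_set(emb, seeds, top_k=6)

print(f"vocabulary: {len(emb.words)} words, dim={emb.dim}")
print("\ntop candidates (word, max cosine to a seed, nearest seed):")
for word, score, nearest in candidates:
    print(f"  {word:10s} {score:+.3f}  ({nearest})")

accepted = [w for w, _, _ in candidates if w in synonyms]
lexicon = h.curate_lexicon(seeds, candidates, accepted)
print(f"\ncurated lexicon ({len(lexicon)} words): {sorted(lexicon.curated)}")
# Planted synonyms should carry scores near +1 and rank above every
# distractor; curation (the accept list) keeps only verified words.
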