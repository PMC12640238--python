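Tâche : décider si l'exemple correspond à la relation {relation} ou non.
Définition de {relation} : {definition}
Réponds {relation} si la relation est présente entre le phénotype balisé et
l'expression temporelle balisée, sinon réponds NONE.
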