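Tâche : déterminer la relation temporelle entre le phénotype balisé et
l'expression temporelle balisée. Classe la relation dans l'un des 7 types
définis ({labels}) ou NONE si aucune relation temporelle n'existe.
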