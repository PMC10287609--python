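preferred_label,cui,concept_index,synonyms
Lung carcinoma,C0684249,1,"ca lung|ca. lung|carcinoma lung|lung carcinoma|lung ca|adenoca lung|adenocarcinoma lung|lung adenocarcinoma|sqaumous cell ca lung|sqaumous cell carcinoma lung"
Non-small cell lung carcinoma,C0007131,2,"nsclc|nsclc,|nsclc;|nsclc.|nsclc)|non small cell lung carcinoma.|non small cell lung carcinoma|non small cell lung ca|non small cell lung ca."
Small cell lung carcinoma,C0149925,3,"sclc|small cell lung carcinoma|small cell lung ca"
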